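import numpy as np
import pandas as pd
import pytest

from trophotax import synthetic
from trophotax.trees import Phylogeny


@pytest.fixture
def cherry():
    """Two tips with equal branches under a root of depth 2."""
    return Phylogeny.from_newick("(A:2,B:2);")


@pytest.fixture
def eight_tip_tree():
    """A fixed 8-tip tree with varied branch lengths for oracle checks."""
    return Phylogeny.from_newick(
        "(((A:1.2,B:0.8):0.5,(C:0.4,D:1.6):0.9):0.7,"
        "((E:0.6,F:1.4):1.1,(G:0.9,H:1.1):0.3):0.2);"
    )


@pytest.fixture
def polytomy_tree():
    """Seven tips with a basal 4-tomy and a cherry."""
    return Phylogeny.from_newick("((A:1,B:1,C:1,D:1):1,(E:0.5,F:0.5):1.5,G:2);")


@pytest.fixture(scope="session")
def yule100():
    """A 100-tip ultrametric pure-birth tree shared by simulation tests."""
    return synthetic.simulate_yule_tree(100, 1.0, seed=7)


@pytest.fixture
def star_traits():
    """i.i.d. trait draws with an index, for non-phylogenetic checks."""
    rng = np.random.default_rng(0)
    idx = [f"t{i}" for i in range(1, 41)]
    return pd.DataFrame(rng.normal(size=(40, 3)), index=idx, columns=list("xyz"))
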