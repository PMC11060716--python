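"""Time-scaling, polytomy resolution and BM ancestral state estimation."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from trophotax import synthetic
from trophotax.ancestors import (
    anc_states_bm,
    averaged_asr,
    node_key,
    resolve_polytomies,
    timescale_tree,
)
from trophotax.trees import Phylogeny, PhylogenyError


class TestTimescale:
    def test_two_coeval_tips_under_pinned_root(self):
        topo = Phylogeny.from_newick("((A,B),C);")
        tree = timescale_tree(topo, {"A": 120, "B": 120, "C": 120}, 144)
        assert tree.height == pytest.approx(24.0)

    def test_minimum_divergence_offset_in_ma(self):
        topo = Phylogeny.from_newick("(((A,B),C),D);")
        tree = timescale_tree(
            topo, {"A": 120, "B": 120, "C": 120, "D": 120}, 144, 1000
        )
        internal_edges = [
            n.edge.length
            for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        ]
        assert min(internal_edges) == pytest.approx(0.001)
        # every branch at least the offset
        lengths = [
            n.edge.length
            for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None
        ]
        assert min(lengths) >= 0.001 - 1e-12

    def test_tip_older_than_root_rejected(self):
        topo = Phylogeny.from_newick("((A,B),C);")
        with pytest.raises(PhylogenyError, match="older"):
            timescale_tree(topo, {"A": 145, "B": 120, "C": 120}, 144)

    def test_staggered_tip_ages(self):
        topo = Phylogeny.from_newick("((A,B),C);")
        tree = timescale_tree(topo, {"A": 119, "B": 121, "C": 124}, 144)
        depths = tree.node_depths()
        ages = {
            (l.taxon.label): 144 - depths[l] for l in tree.tree.leaf_node_iter()
        }
        assert ages == pytest.approx({"A": 119, "B": 121, "C": 124})


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self, eight_tip_tree):
        resolved = resolve_polytomies(eight_tip_tree, seed=0)
        assert resolved.as_newick() == eight_tip_tree.as_newick()

    def test_trichotomy_resolutions_uniform(self):
        tree = Phylogeny.from_newick("((A:1,B:1,C:1):1,D:2);")
        counts = Counter()
        n = 10000
        for s in range(n):
            r = resolve_polytomies(tree, seed=s)
            pair = next(
                k for k in r.node_keys().values() if len(k) == 2 and "D" not in k
            )
            counts[tuple(sorted(pair))] += 1
        for pair, c in counts.items():
            assert abs(c / n - 1 / 3) < 0.02

    @pytest.mark.parametrize("k", [3, 4, 6])
    def test_ktomy_gains_k_minus_two_nodes(self, k):
        tips = ",".join(f"t{i}:1" for i in range(k))
        tree = Phylogeny.from_newick(f"({tips});")
        resolved = resolve_polytomies(tree, seed=1)
        assert resolved.is_binary()
        assert resolved.n_internal == tree.n_internal + k - 2

    def test_tip_depths_preserved(self, polytomy_tree):
        resolved = resolve_polytomies(polytomy_tree, seed=5)
        d0 = polytomy_tree.node_depths()
        d1 = resolved.node_depths()
        for leaf in polytomy_tree.tree.leaf_node_iter():
            lab = leaf.taxon.label
            match = next(
                l for l in resolved.tree.leaf_node_iter() if l.taxon.label == lab
            )
            assert d1[match] == pytest.approx(d0[leaf], rel=1e-6)


def brute_force_gls_states(tree, y):
    """Independent oracle: per-node conditional means via explicit inverses."""
    labels = list(y.index)
    C = tree.vcv(labels=labels).to_numpy()
    Ci = np.linalg.inv(C)
    one = np.ones(len(labels))
    yv = y.to_numpy(dtype=float)
    mu = (one @ Ci @ yv) / (one @ Ci @ one)
    depths = tree.node_depths()
    keys = tree.node_keys()

    def leafset(n):
        return {(l.taxon.label if l.taxon else l.label) for l in n.leaf_iter()}

    out = {}
    for node, tipset in keys.items():
        cv = np.empty(len(labels))
        for j, lab in enumerate(labels):
            p = node  # walk rootward until the tip is below p: that is the MRCA
            while lab not in leafset(p):
                p = p.parent_node
            cv[j] = depths[p]
        w = cv @ Ci
        out[node_key(tipset)] = w @ yv + (1 - w @ one) * mu
    return out


class TestAncStatesBM:
    def test_cherry_root_is_midpoint(self, cherry):
        y = pd.Series({"A": 2.0, "B": 6.0}, name="trait")
        states = anc_states_bm(cherry, y)
        root = states.table[("trait", "mean")].loc[node_key(["A", "B"])]
        assert root == pytest.approx(4.0)

    def test_matches_brute_force_gls_oracle(self, eight_tip_tree):
        for seed in range(3):
            y = synthetic.simulate_bm_traits(
                eight_tip_tree, 1.0, 0.0, seed=seed
            ).data["trait"]
            states = anc_states_bm(eight_tip_tree, y)
            oracle = brute_force_gls_states(eight_tip_tree, y)
            for key, val in oracle.items():
                assert states.table[("trait", "mean")].loc[key] == pytest.approx(
                    val, abs=1e-10
                )

    def test_root_equals_gls_phylogenetic_mean(self, eight_tip_tree):
        y = synthetic.simulate_bm_traits(eight_tip_tree, 2.0, 1.0, seed=7).data[
            "trait"
        ]
        C = eight_tip_tree.vcv(labels=list(y.index)).to_numpy()
        Ci = np.linalg.inv(C)
        one = np.ones(len(y))
        mu = (one @ Ci @ y.to_numpy()) / (one @ Ci @ one)
        states = anc_states_bm(eight_tip_tree, y)
        root = states.table[("trait", "mean")].loc[node_key(y.index)]
        assert root == pytest.approx(mu, abs=1e-10)

    def test_ci_brackets_mean(self, eight_tip_tree):
        y = synthetic.simulate_bm_traits(eight_tip_tree, 1.0, 0.0, seed=2).data
        states = anc_states_bm(eight_tip_tree, y)
        t = states.table
        assert (t[("trait", "ci_low")] <= t[("trait", "mean")]).all()
        assert (t[("trait", "mean")] <= t[("trait", "ci_high")]).all()
        assert states.sigma2["trait"] > 0

    def test_zero_length_terminal_branch_rejected(self):
        tree = Phylogeny.from_newick("((A:0,B:1):1,C:2);")
        y = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(PhylogenyError, match="terminal"):
            anc_states_bm(tree, y)

    def test_parameter_recovery_at_scale(self, yule100):
        # sigma^2 ML bias and root CI coverage under the generating model
        rootkey = node_key(yule100.tip_labels)
        sigs, cover = [], 0
        reps = 500
        for r in range(reps):
            tr = synthetic.simulate_bm_traits(yule100, 2.0, 5.0, seed=r)
            st = anc_states_bm(yule100, tr.data["trait"])
            sigs.append(st.sigma2["trait"])
            lo = st.table[("trait", "ci_low")].loc[rootkey]
            hi = st.table[("trait", "ci_high")].loc[rootkey]
            cover += lo <= 5.0 <= hi
        assert abs(np.mean(sigs) / 2.0 - 1) < 0.10
        assert 0.92 <= cover / reps <= 0.98


class TestAveragedASR:
    def test_binary_tree_has_zero_spread(self, eight_tip_tree):
        y = synthetic.simulate_bm_traits(eight_tip_tree, 1.0, 0.0, seed=1).data
        st = averaged_asr(eight_tip_tree, y, n_resolutions=20, seed=0)
        spread = (
            st.table[("trait", "q97.5")] - st.table[("trait", "q2.5")]
        ).abs()
        assert (spread < 1e-12).all()

    def test_polytomy_root_stable_across_resolutions(self, polytomy_tree):
        X = pd.DataFrame(
            {"m": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]}, index=list("ABCDEFG")
        )
        st = averaged_asr(polytomy_tree, X, n_resolutions=1000, seed=1)
        root = node_key(list("ABCDEFG"))
        mean = st.table[("m", "mean")].loc[root]
        spread = st.table[("m", "q97.5")].loc[root] - st.table[("m", "q2.5")].loc[root]
        assert abs(spread / mean) < 1e-6

    def test_identical_sister_probabilities_interpolate(self):
        # short terminal branches: the parent's state is pinned to its tips
        tree = Phylogeny.from_newick(
            "((A:0.01,B:0.01):1.99,(C:0.01,D:0.01):1.99);"
        )
        probs = pd.DataFrame(
            {
                "invertivore": [1.0, 1.0, 0.0, 0.0],
                "herbivore": [0.0, 0.0, 1.0, 1.0],
            },
            index=list("ABCD"),
        )
        st = averaged_asr(tree, probs, n_resolutions=5, seed=0, renormalise=True)
        ab = st.table.loc[node_key(["A", "B"])]
        assert ab[("invertivore", "renormalised")] == pytest.approx(1.0, abs=0.02)
        # renormalised node vectors sum to one
        ren = st.table[
            [("invertivore", "renormalised"), ("herbivore", "renormalised")]
        ].to_numpy()
        assert np.allclose(ren.sum(axis=1), 1.0)

    def test_seed_only_permutes_not_biases(self, polytomy_tree):
        X = pd.DataFrame({"m": np.arange(7, dtype=float)}, index=list("ABCDEFG"))
        a = averaged_asr(polytomy_tree, X, n_resolutions=200, seed=1)
        b = averaged_asr(polytomy_tree, X, n_resolutions=200, seed=2)
        root = node_key(list("ABCDEFG"))
        ra = a.table[("m", "mean")].loc[root]
        rb = b.table[("m", "mean")].loc[root]
        assert abs(ra - rb) / abs(ra) < 1e-6
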