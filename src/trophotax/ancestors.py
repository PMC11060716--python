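"""Time-scaling, polytomy resolution and Brownian-motion ancestral states.

Fossil trees arrive as topologies with first-occurrence tip ages; they
are time-scaled by pinning the root, placing each internal node a
minimum divergence time above its oldest descendant, and fixing tips at
their ages.  Ancestral states are maximum-likelihood estimates under
Brownian motion (the generalised-least-squares conditional means, the
same quantity phytools' fastAnc computes), with polytomies handled by
averaging over many random bifurcating resolutions whose inserted edges
are negligibly short.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .trees import Phylogeny, PhylogenyError

__all__ = [
    "AncStates",
    "node_key",
    "timescale_tree",
    "resolve_polytomies",
    "anc_states_bm",
    "averaged_asr",
]

#: Fraction of tree height used for edges inserted when resolving polytomies.
EPSILON_FRACTION = 1e-8


@dataclass
class AncStates:
    """Per-internal-node ancestral estimates.

    ``table`` is indexed by node keys (sorted '|'-joined descendant tip
    labels).  For a single resolved tree it holds the estimate, its
    variance and 95% CI per trait; for resolution-averaged runs it holds
    the mean of means and the 2.5/97.5% quantiles across resolutions.
    """

    table: pd.DataFrame
    sigma2: dict
    n_resolutions: int = 1


def node_key(tips) -> str:
    return "|".join(sorted(tips))


# ----------------------------------------------------------------------
# time-scaling
# ----------------------------------------------------------------------

def timescale_tree(
    topology: Phylogeny,
    tip_ages: dict,
    root_age: float,
    divergence_offset_yr: float = 1000.0,
) -> Phylogeny:
    """Assign branch lengths (Ma) from tip ages and a fixed root age.

    Tips sit at their first-occurrence ages (Ma before present); each
    internal node is placed ``divergence_offset_yr`` (converted to Ma)
    above its oldest child, and the root is pinned at ``root_age``.
    Raises if a tip is older than the root or the minimum node ages
    already exceed it.
    """
    offset = divergence_offset_yr / 1e6
    tree = topology.tree.clone(depth=1)
    ages: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            if label not in tip_ages:
                raise PhylogenyError(f"no age for tip {label!r}")
            age = float(tip_ages[label])
            if age > root_age:
                raise PhylogenyError(
                    f"tip {label!r} ({age} Ma) is older than the root ({root_age} Ma)"
                )
            ages[node] = age
        else:
            ages[node] = max(ages[c] for c in node.child_nodes()) + offset
    root = tree.seed_node
    if ages[root] > root_age:
        raise PhylogenyError(
            f"minimum root age {ages[root]:.6f} Ma exceeds the requested "
            f"root age {root_age} Ma (negative branch implied)"
        )
    ages[root] = float(root_age)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = ages[node.parent_node] - ages[node]
            if length < 0:
                raise PhylogenyError("negative branch implied by tip ages")
            node.edge.length = length
    return Phylogeny(tree)


# ----------------------------------------------------------------------
# polytomy resolution
# ----------------------------------------------------------------------

def resolve_polytomies(tree: Phylogeny, seed: int = 0) -> Phylogeny:
    """Replace each polytomy by a random sequence of bifurcations.

    Pairs of children are merged uniformly at random until the node is
    binary (a k-tomy gains k - 2 internal nodes); inserted nodes hang a
    tiny epsilon (1e-8 of tree height) below their parent, with the
    original child edges shortened to match, so tip depths are preserved
    to that tolerance.  A binary input is returned unchanged (as a copy).
    """
    rng = np.random.default_rng(seed)
    out = tree.tree.clone(depth=1)
    has_lengths = any(
        n.edge.length is not None
        for n in out.preorder_node_iter()
        if n.parent_node is not None
    )
    eps = EPSILON_FRACTION * tree.height if has_lengths else None
    for node in list(out.preorder_node_iter()):
        original_children = node.child_nodes()
        if len(original_children) <= 2:
            continue
        items = list(original_children)
        inserted = []
        while len(items) > 2:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            a, b = items.pop(j), items.pop(i)  # pop the larger index first
            node.remove_child(a)
            node.remove_child(b)
            merged = dendropy.Node()
            merged.add_child(a)
            merged.add_child(b)
            node.add_child(merged)
            items.append(merged)
            inserted.append(merged)
        if eps is None:
            continue
        for m in inserted:
            m.edge.length = eps
        for child in original_children:
            steps = 0
            p = child.parent_node
            while p is not node:
                steps += 1
                p = p.parent_node
            if steps:
                newlen = child.edge.length - steps * eps
                if newlen <= 0:
                    raise PhylogenyError(
                        "edge too short to absorb the polytomy-resolution epsilon"
                    )
                child.edge.length = newlen
    return Phylogeny(out)


# ----------------------------------------------------------------------
# ML Brownian-motion ancestral states
# ----------------------------------------------------------------------

def _node_tip_cov(tree: Phylogeny, labels: list[str]):
    """Covariances of internal nodes with tips, plus node self-variances.

    Returns (internal_nodes, keys, cross, self_var) where
    ``cross[v, j] = depth(MRCA(node_v, tip_j))`` and ``self_var[v]`` is
    the node's own root-to-node depth.
    """
    depths = tree.node_depths()
    index = {lab: i for i, lab in enumerate(labels)}
    leafsets: dict = {}
    rows = []
    internal = []
    keys = []
    node_keys_map = tree.node_keys()
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label if node.taxon is not None else node.label
            leafsets[node] = [index[lab]] if lab in index else []
        else:
            leafsets[node] = [i for c in node.child_nodes() for i in leafsets[c]]
    n = len(labels)
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        internal.append(node)
        keys.append(node_key(node_keys_map[node]))
        row = np.empty(n)
        # tips below this node share its full depth; others share the depth
        # of the MRCA, found by walking toward the root
        below = set(leafsets[node])
        row[list(below)] = depths[node]
        p = node
        while p.parent_node is not None:
            p = p.parent_node
            newly = [i for i in leafsets[p] if i not in below]
            row[newly] = depths[p]
            below.update(newly)
        rows.append(row)
    cross = np.vstack(rows)
    self_var = np.array([depths[v] for v in internal])
    return internal, keys, cross, self_var


def anc_states_bm(tree: Phylogeny, x) -> AncStates:
    """ML ancestral states under Brownian motion, with variances and CIs.

    Equivalent to the GLS conditional mean at each internal node given
    the tips, with the root state estimated by the phylogenetic
    (GLS) mean and the rate sigma^2 by maximum likelihood.  Requires a
    value for every tip and strictly positive terminal branches.
    """
    if isinstance(x, pd.Series):
        x = x.to_frame()
    x = pd.DataFrame(x)
    labels = list(x.index)
    missing = set(tree.tip_labels) - set(labels)
    if missing:
        raise ValueError(f"tips without trait values: {sorted(missing)}")
    for leaf in tree.tree.leaf_node_iter():
        if not leaf.edge.length:
            raise PhylogenyError(
                "zero-length terminal branch; adjust epsilon before reconstruction"
            )
    C = tree.vcv(labels=labels).to_numpy()
    n = C.shape[0]
    cf = cho_factor(C)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    s = one @ Ci1
    internal, keys, cross, self_var = _node_tip_cov(tree, labels)
    W = cho_solve(cf, cross.T).T  # rows: c_v' C^-1
    w1 = W @ one
    records = {}
    sigma2 = {}
    for col in x.columns:
        y = x[col].to_numpy(dtype=float)
        mu = (Ci1 @ y) / s
        resid = y - mu
        sig2 = float(resid @ cho_solve(cf, resid) / n)
        if sig2 <= 0:
            sig2 = np.finfo(float).tiny
        est = W @ y + (1.0 - w1) * mu
        var = sig2 * (self_var - np.einsum("ij,ij->i", W, cross) + (1.0 - w1) ** 2 / s)
        var = np.maximum(var, 0.0)
        se = np.sqrt(var)
        records[(col, "mean")] = est
        records[(col, "variance")] = var
        records[(col, "ci_low")] = est - 1.96 * se
        records[(col, "ci_high")] = est + 1.96 * se
        sigma2[col] = sig2
    table = pd.DataFrame(records, index=pd.Index(keys, name="node"))
    return AncStates(table=table, sigma2=sigma2, n_resolutions=1)


def averaged_asr(
    tree: Phylogeny,
    X,
    n_resolutions: int = 10000,
    seed: int = 0,
    renormalise: bool = False,
) -> AncStates:
    """Average ML ancestral states over random polytomy resolutions.

    Only nodes present in the unresolved tree (matched by descendant tip
    set) are reported, with the mean and the 2.5/97.5% quantiles of the
    per-resolution estimates.  With ``renormalise=True`` (for diet
    probability codings) each node's per-column means are clipped at
    zero and rescaled to sum to one; the raw per-column means are kept
    alongside.
    """
    if isinstance(X, pd.Series):
        X = X.to_frame()
    X = pd.DataFrame(X)
    base_keys = [node_key(k) for k in tree.node_keys().values()]
    rng = np.random.default_rng(seed)
    acc: dict = {key: {col: [] for col in X.columns} for key in base_keys}
    sig_acc = {col: [] for col in X.columns}
    for _ in range(n_resolutions):
        res = resolve_polytomies(tree, seed=int(rng.integers(2**31 - 1)))
        states = anc_states_bm(res, X)
        for col in X.columns:
            sig_acc[col].append(states.sigma2[col])
            series = states.table[(col, "mean")]
            for key in base_keys:
                if key in series.index:
                    acc[key][col].append(series.loc[key])
    matched = [k for k in base_keys if all(len(acc[k][c]) == n_resolutions for c in X.columns)]
    unmatched = set(base_keys) - set(matched)
    if unmatched:
        raise PhylogenyError(
            f"nodes not matched across resolutions: {sorted(unmatched)}"
        )
    records = {}
    for col in X.columns:
        vals = np.array([acc[k][col] for k in base_keys])  # nodes x resolutions
        records[(col, "mean")] = vals.mean(axis=1)
        records[(col, "q2.5")] = np.quantile(vals, 0.025, axis=1)
        records[(col, "q97.5")] = np.quantile(vals, 0.975, axis=1)
    table = pd.DataFrame(records, index=pd.Index(base_keys, name="node"))
    if renormalise:
        means = table[[(c, "mean") for c in X.columns]].to_numpy()
        clipped = np.clip(means, 0.0, None)
        totals = clipped.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        normed = clipped / totals
        for j, col in enumerate(X.columns):
            table[(col, "renormalised")] = normed[:, j]
    sigma2 = {col: float(np.mean(v)) for col, v in sig_acc.items()}
    return AncStates(table=table, sigma2=sigma2, n_resolutions=n_resolutions)
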