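"""Rooted phylogenies with branch lengths in Ma.

Thin wrapper around :mod:`dendropy` providing the validation and matrix
helpers the comparative statistics need: unique tip labels, non-negative
edge lengths, polytomy-tolerant traversal, and the shared-path-length
(Brownian-motion) covariance matrix.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd

__all__ = ["Phylogeny", "PhylogenyError", "read_tree"]


class PhylogenyError(ValueError):
    """Raised for malformed or unsupported tree input."""


class Phylogeny:
    """A rooted tree with tip labels and edge lengths in Ma.

    Polytomies are permitted and preserved.  Edge lengths may be absent
    (topology-only trees, e.g. before time-scaling) but never negative.
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None:
            raise PhylogenyError("tree has no root node")
        labels = []
        for leaf in tree.leaf_node_iter():
            label = None
            if leaf.taxon is not None:
                label = leaf.taxon.label
            elif leaf.label is not None:
                label = leaf.label
            if label is None:
                raise PhylogenyError("unlabelled tip in tree")
            labels.append(label)
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise PhylogenyError(f"negative edge length {edge.length}")
        self.tree = tree
        self._labels = labels

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter() if not n.is_leaf())

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self.tree.preorder_node_iter()
            if not n.is_leaf()
        )

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    # ------------------------------------------------------------------
    # depths / covariance
    # ------------------------------------------------------------------
    def node_depths(self) -> dict:
        """Distance from the root for every node (root edge ignored)."""
        depths = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                el = node.edge.length
                if el is None:
                    raise PhylogenyError("edge length missing; tree is not scaled")
                depths[node] = depths[node.parent_node] + el
        return depths

    @property
    def height(self) -> float:
        depths = self.node_depths()
        return max(depths[leaf] for leaf in self.tree.leaf_node_iter())

    def _leaf_label(self, leaf) -> str:
        return leaf.taxon.label if leaf.taxon is not None else leaf.label

    def vcv(self, lam: float = 1.0, labels: list[str] | None = None) -> pd.DataFrame:
        """Shared-path-length covariance C with Pagel's lambda on off-diagonals.

        ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
        diagonal holds root-to-tip depths and is untouched by ``lam``.
        """
        if not 0.0 <= lam <= 1.0:
            raise PhylogenyError(f"lambda must be in [0, 1], got {lam}")
        depths = self.node_depths()
        order = labels if labels is not None else self.tip_labels
        index = {lab: i for i, lab in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))
        # leaf index sets per node, bottom-up
        leafsets: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                lab = self._leaf_label(node)
                if lab not in index:
                    leafsets[node] = []
                    continue
                i = index[lab]
                C[i, i] = depths[node]
                leafsets[node] = [i]
            else:
                kids = [leafsets[c] for c in node.child_nodes()]
                d = depths[node]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = d
                leafsets[node] = [i for k in kids for i in k]
        missing = [lab for lab in order if lab not in {self._leaf_label(l) for l in self.tree.leaf_node_iter()}]
        if missing:
            raise PhylogenyError(f"tips not in tree: {missing}")
        if lam != 1.0:
            off = ~np.eye(n, dtype=bool)
            C[off] *= lam
        return pd.DataFrame(C, index=order, columns=order)

    def node_keys(self) -> dict:
        """Map each internal node to the frozenset of its descendant tips."""
        keys = {}
        sets: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                sets[node] = frozenset([self._leaf_label(node)])
            else:
                sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
                keys[node] = sets[node]
        return keys

    # ------------------------------------------------------------------
    # serialisation
    # ------------------------------------------------------------------
    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path, schema: str = "newick") -> None:
        self.tree.write(path=str(path), schema=schema, suppress_rooting=True)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        return _parse(io.StringIO(newick), "newick")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {self.n_internal} internal nodes>"


def _parse(stream, schema: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            file=stream, schema=schema, rooting="default-rooted",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"could not parse {schema} tree: {exc}") from exc
    if not tree.is_rooted:
        raise PhylogenyError(
            "tree is explicitly unrooted; root it (e.g. replace [&U] with [&R]) "
            "before analysis"
        )
    return Phylogeny(tree)


def read_tree(path, format: str = "newick") -> Phylogeny:
    """Read a rooted Newick/NEXUS tree, preserving polytomies.

    Raises
    ------
    PhylogenyError
        For unparseable input, explicitly unrooted trees, or duplicate
        tip labels.
    """
    if format not in ("newick", "nexus"):
        raise PhylogenyError(f"unsupported tree format: {format}")
    with open(path) as fh:
        return _parse(fh, format)
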