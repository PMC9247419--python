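"""Phylogenetic trees and Brownian-motion trait covariance.

A :class:`PhyloTree` is a thin wrapper around a rooted dendropy tree with
branch lengths in millions of years.  Under a Brownian-motion (BM) model of
trait evolution the expected covariance between the trait values of two
species equals the branch length they share on the path from the root to
their most recent common ancestor; :func:`brownian_covariance` builds that
matrix, and :func:`lambda_transform` applies Pagel's λ, which rescales only
the off-diagonal (shared-history) part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class PhyloTree:
    """Rooted leaf-labeled tree with non-negative branch lengths.

    Polytomies are permitted; leaf labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self._leaf_labels = labels

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @classmethod
    def from_newick(cls, text: str, default_branch_length: float | None = None) -> "PhyloTree":
        return parse_newick(text, default_branch_length=default_branch_length)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length for every leaf."""
        depths: dict[str, float] = {}
        for node, d in self._iter_depths():
            if node.is_leaf():
                depths[node.taxon.label] = d
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = np.asarray(list(self.leaf_depths().values()))
        return bool(np.ptp(d) <= tol) if d.size else True

    def _iter_depths(self):
        tree = self._tree
        depth = {tree.seed_node: tree.seed_node.edge.length or 0.0}
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
            yield node, depth[node]


def parse_newick(text: str, default_branch_length: float | None = None) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Every edge must carry a branch length unless ``default_branch_length``
    supplies a fallback.  Malformed input raises :class:`NewickParseError`
    with the underlying position information.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            if default_branch_length is None:
                label = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(
                    f"missing branch length on edge above {label!r}; "
                    "pass default_branch_length to allow"
                )
            node.edge.length = default_branch_length
    return PhyloTree(tree)


@dataclass
class CovModel:
    """Species-by-species trait covariance under BM, with Pagel's λ.

    ``matrix[i, j]`` is the shared root-to-MRCA branch length of leaves
    ``labels[i]`` and ``labels[j]``, off-diagonals scaled by ``lam``.
    """

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)
    lam: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def brownian_covariance(tree: PhyloTree) -> CovModel:
    """BM covariance: C[i,j] = shared branch length from root to MRCA(i, j).

    Built by accumulating each branch's length over the outer product of the
    leaf-membership indicator of the clade below it, which handles polytomies
    natively and costs O(nodes · n²) in vectorized numpy.
    """
    if tree.n_leaves < 2:
        raise ValueError("covariance requires at least 2 leaves")
    labels = tree.leaf_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    dtree = tree.dendropy_tree
    # leaves below each node, bottom-up
    below: dict[object, np.ndarray] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(n, dtype=bool)
            mask[index[node.taxon.label]] = True
        else:
            mask = np.zeros(n, dtype=bool)
            for child in node.child_nodes():
                mask |= below[child]
        below[node] = mask
        length = node.edge.length or 0.0
        if node is dtree.seed_node:
            length = node.edge.length or 0.0  # root edge, if any, shifts all entries
        if length > 0:
            C[np.ix_(mask, mask)] += length
    if np.max(np.diag(C)) <= 0:
        raise ValueError("zero-depth tree: covariance is degenerate")
    return CovModel(matrix=C, labels=labels, lam=1.0)


def lambda_transform(cov: CovModel, lam: float) -> CovModel:
    """Scale off-diagonal covariance by Pagel's λ ∈ [0, 1]; diagonal untouched."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    d = np.diag(np.diag(cov.matrix))
    m = lam * (cov.matrix - d) + d
    return CovModel(matrix=m, labels=list(cov.labels), lam=lam * cov.lam)
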