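"""Rooted trees and the Brownian-motion species covariance.

Under a Brownian trait-evolution model the covariance of two tips equals the
branch length shared on their root-to-tip paths, i.e. the depth of their most
recent common ancestor.  The model consumes an (S-1) x (S-1) covariance with
the reference taxon's row/column removed, scaled by a positive constant ``c``;
with no tree available the covariance falls back to ``c * I``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "SpeciesCovariance",
    "read_newick",
    "brownian_covariance",
    "model_covariance",
]


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree with branch lengths, thinly wrapping :class:`dendropy.Tree`."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has a branch with no length; lengths are required")
            if edge.length < 0:
                raise ValueError("branch lengths must be nonnegative")

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(self.to_newick() + "\n")

    def scaled_to_unit_height(self) -> "PhyloTree":
        """Return a copy with all branch lengths divided by the maximum root-to-tip depth."""
        clone = self.tree.clone(depth=1)
        depths = clone.calc_node_root_distances(return_leaf_distances_only=True)
        height = max(depths)
        if height <= 0:
            raise ValueError("tree height is zero; cannot rescale")
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / height
        return PhyloTree(clone)


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string (branch lengths required) into a rooted tree."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise ValueError("newick string contains no tips")
    return PhyloTree(tree)


def read_newick_file(path) -> PhyloTree:
    from pathlib import Path

    return read_newick(Path(path).read_text())


def brownian_covariance(tree: PhyloTree, taxa_order: Sequence[str]) -> np.ndarray:
    """Build the S x S Brownian covariance: entry (s, s') is the depth of MRCA(s, s').

    Diagonal entries are root-to-tip path lengths; no ultrametric normalization
    is applied (non-ultrametric trees are legal, their diagonals simply differ).
    """
    taxa_order = list(taxa_order)
    tips = {leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()}
    missing = [t for t in taxa_order if t not in tips]
    if missing:
        raise KeyError(f"taxa not found in tree: {missing}")

    # depth of every node (sum of branch lengths from the root)
    depth: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    # root-to-tip ancestor chains, root first
    chains: list[list] = []
    for label in taxa_order:
        chain = []
        node = tips[label]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains.append(chain[::-1])

    s = len(taxa_order)
    cov = np.zeros((s, s))
    for i in range(s):
        cov[i, i] = depth[id(chains[i][-1])]
        for j in range(i + 1, s):
            # deepest node common to both chains = MRCA
            k = 0
            limit = min(len(chains[i]), len(chains[j]))
            while k < limit and chains[i][k] is chains[j][k]:
                k += 1
            mrca = chains[i][k - 1]
            cov[i, j] = cov[j, i] = depth[id(mrca)]
    return cov


@dataclass(frozen=True)
class SpeciesCovariance:
    """The (S-1) x (S-1) covariance ``c * Sigma`` entering the MVN likelihood."""

    values: np.ndarray
    taxon_ids: list
    scale_c: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        k = len(self.taxon_ids)
        if values.shape != (k, k):
            raise ValueError("covariance shape does not match taxon labels")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigs = np.linalg.eigvalsh(values)
        if eigs[0] < -1e-8 * max(eigs[-1], 1.0):
            raise ValueError("covariance must be positive semi-definite")
        if self.scale_c <= 0:
            raise ValueError("scale_c must be > 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "taxon_ids", list(self.taxon_ids))

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.taxon_ids)

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="taxon_id")


def model_covariance(
    full: np.ndarray | None,
    taxon_ids: Sequence[str],
    reference_taxon: str,
    scale_c: float = 1.0,
) -> SpeciesCovariance:
    """Drop the reference taxon's row/column from the full covariance and scale by ``c``.

    ``full`` is the S x S covariance whose rows/columns follow ``taxon_ids``;
    pass ``None`` for the no-tree case, which yields ``c`` times the
    (S-1) x (S-1) identity.
    """
    if scale_c <= 0:
        raise ValueError("scale_c must be > 0")
    taxon_ids = list(taxon_ids)
    if reference_taxon not in taxon_ids:
        raise KeyError(f"reference taxon {reference_taxon!r} not among taxa")
    keep_labels = [t for t in taxon_ids if t != reference_taxon]
    if full is None:
        values = scale_c * np.eye(len(keep_labels))
        return SpeciesCovariance(values, keep_labels, scale_c)
    full = np.asarray(full, dtype=float)
    if full.shape != (len(taxon_ids), len(taxon_ids)):
        raise ValueError("full covariance shape does not match taxon labels")
    keep = [i for i, t in enumerate(taxon_ids) if t != reference_taxon]
    values = scale_c * full[np.ix_(keep, keep)]
    return SpeciesCovariance(values, keep_labels, scale_c)
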