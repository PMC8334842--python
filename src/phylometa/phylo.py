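"""Phylogenies and the phylogenetic correlation matrix.

Under a Brownian model of trait evolution on a tree, the expected covariance
between two tips is the branch length they share on the path from the root.
Scaling an ultrametric tree to unit height turns that shared-path matrix into
a correlation matrix with unit diagonal, which is what the meta-regression
uses as the covariance structure of the phylogenetic random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloCovariance",
    "read_newick",
    "phylo_correlation",
    "simulate_yule",
    "match_taxa",
    "assign_grafen_lengths",
]


@dataclass
class PhyloCovariance:
    """Taxa-labelled phylogenetic correlation matrix (unit diagonal, PSD)."""

    taxa: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("phylogenetic matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("phylogenetic correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("phylogenetic matrix is not positive semidefinite")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (or file content) into a rooted tree.

    Tip labels must be unique; polytomies are allowed.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"could not parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    return tree


def assign_grafen_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign Grafen branch lengths to a topology without branch lengths.

    Each node gets height (number of descendant tips - 1); branch lengths are
    parent height minus child height, so the result is ultrametric with tips
    at height zero below the root.
    """
    for node in tree.postorder_node_iter():
        n_desc = max(len(node.leaf_nodes()), 1)
        node._grafen_height = n_desc - 1
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(node.parent_node._grafen_height - node._grafen_height)
    return tree


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def phylo_correlation(
    tree: dendropy.Tree, *, ultrametric_tol: float = 1e-6, strict: bool = False
) -> PhyloCovariance:
    """Shared root-to-tip path lengths, scaled to a unit-diagonal correlation.

    Trees whose edges carry no lengths are given Grafen lengths first.
    Non-ultrametric trees are made ultrametric by stretching/truncating each
    terminal branch to the mean root-to-tip depth (with a warning, or an
    error when ``strict``).  Entry (i, j) is the depth of the most recent
    common ancestor of i and j divided by tree height.
    """
    tree = tree.clone(depth=1)
    has_lengths = any(
        e.length is not None for e in tree.preorder_edge_iter() if e.head_node.parent_node
    )
    if not has_lengths:
        assign_grafen_lengths(tree)
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    tip_depths = np.array([depths[l] for l in leaves])
    height = tip_depths.mean()
    if height <= 0:
        raise ValueError("tree has zero height; cannot form a correlation matrix")
    spread = tip_depths.max() - tip_depths.min()
    if spread > ultrametric_tol * height:
        msg = (
            f"tree is not ultrametric (root-to-tip depths span {spread:.4g}); "
            "terminal branches rescaled to the mean depth"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
        for leaf, d in zip(leaves, tip_depths):
            parent_depth = depths[leaf.parent_node]
            new_len = height - parent_depth
            if new_len <= 0:
                raise ValueError(
                    f"cannot ultrametricize: tip {leaf.taxon.label!r} has an "
                    "ancestor deeper than the mean root-to-tip depth"
                )
            leaf.edge.length = new_len
        depths = _node_depths(tree)

    taxa = [l.taxon.label for l in leaves]
    k = len(taxa)
    # depth of the MRCA of every tip pair, via descendant-leaf index sets
    leaf_index = {l: i for i, l in enumerate(leaves)}
    mat = np.zeros((k, k))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = [leaf_index[node]]
            continue
        children = [c._leafset for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    # MRCA depth: deepest node separating i and j is hit first
                    # in postorder, so only fill entries still at zero
                    for j in children[b]:
                        if mat[i, j] == 0.0:
                            mat[i, j] = mat[j, i] = d
        node._leafset = [i for ch in children for i in ch]
    np.fill_diagonal(mat, [depths[l] for l in leaves])
    mat /= height
    # guard against tiny negative eigenvalues from float accumulation
    mat = (mat + mat.T) / 2.0
    return PhyloCovariance(taxa=taxa, matrix=mat)


def simulate_yule(k: int, seed: int) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``k`` tips, height scaled to 1.

    Lineages split at unit rate; a uniformly chosen lineage bifurcates at
    each event.  The tree is ultrametric by construction and deterministic
    for a given seed.  Tips are labelled t1..tk.
    """
    if k < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)
    t = 0.0
    birth_times = {root: 0.0}
    while len(active) < k:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        birth_times[node] = t
        for _ in range(2):
            child = node.new_child(edge_length=0.0)
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    # set branch lengths from birth times; active lineages end at t_end
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_t = birth_times[node.parent_node]
        node.edge.length = (birth_times.get(node, t_end) - parent_t)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(f"t{i}")
    # scale to unit height
    scale = t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= scale
    return tree


def match_taxa(cov: PhyloCovariance, table: pd.DataFrame, species_col: str = "species_id") -> PhyloCovariance:
    """Subset and reorder a correlation matrix to the species of a table."""
    wanted = list(table[species_col])
    index = {t: i for i, t in enumerate(cov.taxa)}
    missing = [s for s in wanted if s not in index]
    if missing:
        raise ValueError(f"species absent from the tree: {missing}")
    idx = np.array([index[s] for s in wanted])
    return PhyloCovariance(taxa=wanted, matrix=cov.matrix[np.ix_(idx, idx)])
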