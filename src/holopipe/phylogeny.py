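"""Core-genome phylogeny: Poisson-corrected distances, neighbor joining,
and column-resampling bootstrap support.

Distances between super-alignment rows are Poisson-corrected protein
distances d = −ln(1 − p) for p-distance p (fraction of mismatching
columns among columns where both rows are ungapped); p is capped at 0.95
with a warning to keep the correction finite.  Tree inference is
Saitou–Nei neighbor joining, exact on additive distance matrices.
Bootstrap support is the percentage of column-resampled replicates whose
NJ tree contains each internal bipartition of the full-data tree.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

P_CAP = 0.95


def _rows_to_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = sorted(alignment)
    lengths = {len(alignment[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    mat = np.vstack([np.frombuffer(alignment[n].encode("ascii"), dtype=np.uint8)
                     for n in names])
    return names, mat


def p_distances(mat: np.ndarray, columns: np.ndarray | None = None) -> np.ndarray:
    """Pairwise p-distances between alignment rows (gap-paired columns skipped)."""
    gap = ord("-")
    sub = mat if columns is None else mat[:, columns]
    n = sub.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (sub[i] != gap) & (sub[j] != gap)
            total = int(ok.sum())
            p = float((sub[i][ok] != sub[j][ok]).sum() / total) if total else 0.0
            d[i, j] = d[j, i] = p
    return d


def poisson_correct(p: np.ndarray) -> np.ndarray:
    """d = −ln(1 − p), with p capped at 0.95 (warned) to stay finite."""
    if np.any(p >= P_CAP):
        warnings.warn(f"p-distance >= {P_CAP}; capped before Poisson correction")
    return -np.log1p(-np.minimum(p, P_CAP))


def neighbor_joining(dist: np.ndarray, ids: list[str]) -> TreeNode:
    """Saitou–Nei NJ tree from a distance matrix (>= 3 taxa)."""
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(DistanceMatrix(dist, ids))


def bipartitions(tree: TreeNode, taxa: list[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised.

    Each internal edge splits the taxa in two; the side not containing the
    lexicographically smallest taxon is used as the canonical representation.
    Splits of size < 2 on either side are trivial and omitted.
    """
    ref = min(taxa)
    all_taxa = frozenset(taxa)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def nj_tree(alignment: dict[str, str], bootstrap_n: int = 100,
            seed: int = 0) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with bootstrap support from a protein super-alignment.

    Returns the tree (internal nodes labelled with integer percent support)
    and the support map for its non-trivial bipartitions.
    """
    names, mat = _rows_to_matrix(alignment)
    if mat.shape[1] == 0:
        raise ValueError("empty alignment")
    tree = neighbor_joining(poisson_correct(p_distances(mat)), names)
    main_splits = bipartitions(tree, names)
    counts = {s: 0 for s in main_splits}
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xB001])
    L = mat.shape[1]
    for _ in range(bootstrap_n):
        cols = rng.integers(0, L, size=L)
        btree = neighbor_joining(poisson_correct(p_distances(mat, cols)), names)
        for s in bipartitions(btree, names):
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / bootstrap_n for s, c in counts.items()} \
        if bootstrap_n > 0 else {s: float("nan") for s in main_splits}

    # annotate internal nodes with their split's support
    ref = min(names)
    all_taxa = frozenset(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_taxa - side
        if side in support:
            node.name = str(int(round(support[side])))
    return tree, support


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()
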