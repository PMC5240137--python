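"""Bin quality scoring against a single-copy marker gene set.

A genome bin is scored by counting, over its contigs, genes that hit a set
of markers expected exactly once per genome:

* completeness  = 100 * (markers present at least once) / marker-set size
* contamination = 100 * (excess copies beyond one, summed) / marker-set size
* heterogeneity = the maximum copy number of any marker (1 if none present)

A bin assembled from two complete, closely related strains therefore scores
completeness 100, contamination 100 and heterogeneity 2 — the signature of
an unresolved strain pair.  This is a flat-marker-set re-expression of the
three scalar quality numbers checkM reports; lineage-specific collocated
marker machinery is deliberately not replicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import gc_content


@dataclass(frozen=True)
class MarkerSet:
    marker_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError("marker set must contain at least one marker")

    @property
    def size(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def from_iterable(cls, ids) -> "MarkerSet":
        return cls(frozenset(ids))


@dataclass
class BinQuality:
    completeness: float       # percent in [0, 100]
    contamination: float      # percent >= 0
    heterogeneity: int        # max marker copy number, >= 1
    marker_counts: dict[str, int]


def marker_counts_for_contigs(contig_ids, gene_table: pd.DataFrame,
                              marker_table: pd.DataFrame) -> dict[str, int]:
    """Copy number of each marker over genes located on the given contigs."""
    contig_ids = set(contig_ids)
    merged = marker_table.merge(gene_table[["gene_id", "contig_id"]], on="gene_id")
    hits = merged[merged["contig_id"].isin(contig_ids)]
    return hits["marker_id"].value_counts().to_dict()


def score_bin(contig_ids, gene_table: pd.DataFrame, marker_table: pd.DataFrame,
              marker_set: MarkerSet) -> BinQuality:
    """Completeness/contamination/heterogeneity of one bin."""
    counts = marker_counts_for_contigs(contig_ids, gene_table, marker_table)
    counts = {m: c for m, c in counts.items() if m in marker_set.marker_ids}
    present = sum(1 for c in counts.values() if c >= 1)
    excess = sum(max(0, c - 1) for c in counts.values())
    het = max(counts.values(), default=1)
    return BinQuality(
        completeness=100.0 * present / marker_set.size,
        contamination=100.0 * excess / marker_set.size,
        heterogeneity=int(het),
        marker_counts=counts,
    )


def n50(lengths) -> int:
    """Length L such that contigs of length >= L sum to >= half the total."""
    ls = sorted((int(x) for x in lengths), reverse=True)
    if not ls:
        return 0
    half = sum(ls) / 2.0
    acc = 0
    for length in ls:
        acc += length
        if acc >= half:
            return length
    return ls[-1]


def quality_report(bins: dict[str, list[str]], contigs: dict[str, str],
                   gene_table: pd.DataFrame, marker_table: pd.DataFrame,
                   marker_set: MarkerSet) -> pd.DataFrame:
    """Per-bin assembly and marker-quality statistics (one row per bin).

    Columns: bin_id, assembly_size, n_contigs, n50, max_contig, gc_pct,
    n_genes, completeness, contamination, heterogeneity.  GC is pooled over
    the bin's concatenated sequence.
    """
    rows = []
    for bin_id, cids in bins.items():
        if not cids:
            raise ValueError(f"bin {bin_id} is empty")
        seqs = [contigs[c] for c in cids]
        lengths = [len(s) for s in seqs]
        q = score_bin(cids, gene_table, marker_table, marker_set)
        in_bin = gene_table["contig_id"].isin(set(cids))
        rows.append({
            "bin_id": bin_id,
            "assembly_size": int(np.sum(lengths)),
            "n_contigs": len(cids),
            "n50": n50(lengths),
            "max_contig": int(np.max(lengths)),
            "gc_pct": 100.0 * gc_content("".join(seqs)),
            "n_genes": int(in_bin.sum()),
            "completeness": q.completeness,
            "contamination": q.contamination,
            "heterogeneity": q.heterogeneity,
        })
    return pd.DataFrame(rows)
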