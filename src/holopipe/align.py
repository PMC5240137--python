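"""Protein global alignment, percent identity, and center-star MSA.

Pairwise alignment is Needleman–Wunsch with BLOSUM62 and affine gaps
(open −11, extend −1, Biopython convention: the first residue of a gap
costs the open score).  Percent identity uses alignment columns — including
gap columns — as the denominator.

The multiple aligner is the classical center-star construction: the center
is the sequence minimizing summed pairwise distance to the others; every
other sequence is aligned to the center pairwise and the pairwise
alignments are merged on the center's coordinates (once a gap, always a
gap).  A gap-fraction column filter (strict by default: any gap drops the
column) then yields well-aligned blocks for concatenation.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

ALLOWED_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


def _check(seq: str) -> None:
    bad = set(seq) - ALLOWED_SYMBOLS
    if bad:
        raise ValueError(f"non-amino-acid symbols in sequence: {sorted(bad)}")
    if not seq:
        raise ValueError("empty sequence")


def align_pair(seq1: str, seq2: str):
    """Best global alignment of two protein sequences (Biopython Alignment)."""
    _check(seq1)
    _check(seq2)
    return _aligner().align(seq1, seq2)[0]


def pairwise_identity(seq1: str, seq2: str) -> tuple[float, float]:
    """Percent identity (matches / alignment columns * 100) and raw score."""
    aln = align_pair(seq1, seq2)
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length, float(aln.score)


def alignment_stats(seq1: str, seq2: str) -> dict:
    """Identity, score, and shorter-sequence coverage of the best alignment."""
    aln = align_pair(seq1, seq2)
    counts = aln.counts()
    shorter = min(len(seq1), len(seq2))
    return {
        "identity": 100.0 * counts.identities / aln.length,
        "score": float(aln.score),
        "coverage": counts.aligned / shorter,
        "columns": aln.length,
    }


def _gapped_pair(center: str, other: str) -> tuple[str, str]:
    aln = align_pair(center, other)
    return str(aln[0]), str(aln[1])


def center_star_align(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star multiple alignment; returns name -> gapped row."""
    names = sorted(seqs)
    if len(names) < 2:
        raise ValueError("center-star alignment needs >= 2 sequences")
    for s in seqs.values():
        _check(s)
    # center = sequence with minimal summed pairwise distance (100 - identity)
    dist_sum = {n: 0.0 for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = 100.0 - pairwise_identity(seqs[a], seqs[b])[0]
            dist_sum[a] += d
            dist_sum[b] += d
    center = min(names, key=lambda n: (dist_sum[n], n))
    c_seq = seqs[center]
    L = len(c_seq)

    # for each other sequence: insertion blocks before each center residue
    # (index 0..L; L = after the last residue) and the character aligned to
    # each center residue
    others = [n for n in names if n != center]
    ins: dict[str, list[str]] = {}
    at_res: dict[str, list[str]] = {}
    for n in others:
        ca, oa = _gapped_pair(c_seq, seqs[n])
        blocks = [""] * (L + 1)
        chars = []
        j = 0
        for cc, oc in zip(ca, oa):
            if cc == "-":
                blocks[j] += oc
            else:
                chars.append(oc)
                j += 1
        ins[n] = blocks
        at_res[n] = chars

    widths = [max((len(ins[n][j]) for n in others), default=0)
              for j in range(L + 1)]
    rows = {n: [] for n in names}
    for j in range(L + 1):
        w = widths[j]
        if w:
            rows[center].append("-" * w)
            for n in others:
                b = ins[n][j]
                rows[n].append(b + "-" * (w - len(b)))
        if j < L:
            rows[center].append(c_seq[j])
            for n in others:
                rows[n].append(at_res[n][j])
    return {n: "".join(parts) for n, parts in rows.items()}


def filter_columns(msa: dict[str, str], max_gap_fraction: float = 0.0
                   ) -> dict[str, str]:
    """Drop alignment columns whose gap fraction exceeds the threshold."""
    names = sorted(msa)
    rows = [msa[n] for n in names]
    n_rows = len(rows)
    keep = [i for i in range(len(rows[0]))
            if sum(r[i] == "-" for r in rows) / n_rows <= max_gap_fraction]
    return {n: "".join(msa[n][i] for i in keep) for n in names}


def align_and_concatenate(core_groups: dict[str, dict[str, str]],
                          max_gap_fraction: float = 0.0
                          ) -> tuple[dict[str, str], dict[str, int]]:
    """Per-group center-star MSA, column filter, and concatenation.

    ``core_groups`` maps group_id -> {genome_id: protein}.  Groups are
    processed in sorted group_id order; groups with fewer than 2 genomes are
    skipped with a warning.  Returns the per-genome super-alignment rows and
    the retained width per group.
    """
    genome_sets = [frozenset(g) for g in core_groups.values() if len(g) >= 2]
    if not genome_sets:
        raise ValueError("no usable core groups")
    genomes = sorted(set.union(*(set(s) for s in genome_sets)))
    parts: dict[str, list[str]] = {g: [] for g in genomes}
    widths: dict[str, int] = {}
    for gid in sorted(core_groups):
        grp = core_groups[gid]
        if len(grp) < 2:
            warnings.warn(f"group {gid} has <2 genomes; skipped")
            continue
        if set(grp) != set(genomes):
            warnings.warn(f"group {gid} missing some genomes; skipped")
            continue
        msa = filter_columns(center_star_align(grp), max_gap_fraction)
        width = len(next(iter(msa.values())))
        widths[gid] = width
        for g in genomes:
            parts[g].append(msa[g])
    return {g: "".join(p) for g, p in parts.items()}, widths
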