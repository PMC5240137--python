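"""Ground-truthed synthetic holobiont metagenome generator.

Generates everything the downstream stages consume — contig FASTA, per-contig
depth in two libraries, read-pair link counts, per-gene proteins, marker and
GO annotation tables, a minimal GO ontology and a truth map — from a
:class:`~holopipe.community.CommunityProfile` and a seed.  Identical seeds
reproduce byte-identical output.

Model choices
-------------
* Genome composition: an order-2 Markov chain over bases per genome, seeded
  from ``tnf_seed`` and calibrated so its stationary GC equals ``gc_target``;
  strains share the parent's chain (they share its sequence).
* Genes: stop-free codon runs drawn from the genome chain, framed by ATG and
  TAA.  Bacterial genomes embed one copy of each shared "core" gene family
  (mutated from a common ancestral sequence) among their private genes; the
  first families double as the single-copy marker set.
* Strains: the parent's genome mutated at a per-base rate calibrated
  analytically (2:1 transition bias) to the requested mean protein identity.
* Contig lengths: log-normal (median 8 kb, truncated at 1 kb), cut only in
  intergenic gaps so genes stay whole.
* Depth: gamma-distributed around the genome's library mean with
  cv^2 = ``dispersion`` (the continuous analogue of a negative-binomial
  count around the mean).
* Links: read-pair counts between adjacent contigs of the same genome plus
  sparse longer-range intra-genome links and a configurable false-link rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import io as hio
from .community import CommunityProfile, GenomeModel
from .features import seq_to_codes
from .util import substream

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)        # A<->G, C<->T
_TRANSVERSION_1 = np.array([1, 0, 1, 0], dtype=np.uint8)    # A->C, C->A, G->C, T->A
_TRANSVERSION_2 = np.array([3, 2, 3, 2], dtype=np.uint8)    # A->T, C->G, G->T, T->C
_STOP_TRIPLES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}           # TAA, TAG, TGA

MEAN_GENE_CODONS = 280
MIN_GENE_CODONS = 80


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# order-2 Markov chain construction and sampling

def _chain_stationary_gc(probs: np.ndarray) -> float:
    """Stationary GC fraction of the 16-state (dinucleotide) chain."""
    t = np.zeros((16, 16))
    for s in range(16):
        for b in range(4):
            t[s, ((s & 3) << 2) | b] = probs[s, b]
    pi = np.full(16, 1 / 16)
    for _ in range(200):
        pi = pi @ t
    base = np.zeros(4)
    for s in range(16):
        base[s & 3] += pi[s]
    return float(base[1] + base[2])


def make_chain(gc_target: float, tnf_seed: int, bias_sigma: float = 0.4) -> np.ndarray:
    """Order-2 transition matrix (16 states x 4 bases), stationary GC calibrated.

    The genome-specific bias is a fixed log-normal perturbation drawn from
    ``tnf_seed``; a scalar GC weight is then solved by bisection so the
    chain's stationary GC matches ``gc_target``.
    """
    bias = np.exp(np.random.default_rng(tnf_seed).normal(0.0, bias_sigma, (16, 4)))

    def chain_for(g: float) -> np.ndarray:
        w = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        p = bias * w
        return p / p.sum(axis=1, keepdims=True)

    lo, hi = 0.02, 0.98
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _chain_stationary_gc(chain_for(mid)) < gc_target:
            lo = mid
        else:
            hi = mid
    return chain_for(0.5 * (lo + hi))


def markov_codes(chain: np.ndarray, n: int, rng: np.random.Generator,
                 init: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Sample ``n`` bases (uint8 codes) from the order-2 chain."""
    if n <= 0:
        return np.empty(0, dtype=np.uint8)
    cum = chain.cumsum(axis=1)
    rows = [tuple(r[:3]) for r in cum]  # thresholds; 4th is 1.0
    u = rng.random(n).tolist()
    out = []
    append = out.append
    p2, p1 = init
    for x in u:
        t0, t1, t2 = rows[(p2 << 2) | p1]
        b = 0 if x < t0 else 1 if x < t1 else 2 if x < t2 else 3
        append(b)
        p2, p1 = p1, b
    return np.array(out, dtype=np.uint8)


def _fix_stops(body: np.ndarray) -> np.ndarray:
    """Remove in-frame stop codons from a CDS body by setting their 3rd base to C."""
    cod = body.reshape(-1, 3)
    is_t = cod[:, 0] == 3
    second = cod[:, 1]
    third = cod[:, 2]
    stop = is_t & (((second == 0) & ((third == 0) | (third == 2)))
                   | ((second == 2) & (third == 0)))
    cod[stop, 2] = 1
    return cod.reshape(-1)


def _translate(cds: np.ndarray) -> str:
    s = codes_to_seq(cds)
    return "".join(_CODON_AA[s[i:i + 3]] for i in range(0, len(s) - len(s) % 3, 3))


# ---------------------------------------------------------------------------
# genome build

@dataclass
class Gene:
    gene_id: str
    family: str
    start: int          # genome coords, 0-based half-open
    end: int
    strand: str         # '+' or '-'


@dataclass
class GenomeBuild:
    """A realised synthetic genome: sequence, layout, contigs and proteins."""

    model: GenomeModel
    codes: np.ndarray
    genes: list[Gene]
    gaps: list[tuple[int, int]]
    contig_bounds: list[tuple[str, int, int]] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)

    @property
    def genome_id(self) -> str:
        return self.model.genome_id

    @property
    def sequence(self) -> str:
        return codes_to_seq(self.codes)

    def contigs(self) -> dict[str, str]:
        return {cid: codes_to_seq(self.codes[s:e])
                for cid, s, e in self.contig_bounds}

    def contig_of(self, position: int) -> str:
        for cid, s, e in self.contig_bounds:
            if s <= position < e:
                return cid
        raise ValueError(f"position {position} outside genome")

    def gene_cds(self, gene: Gene) -> np.ndarray:
        cds = self.codes[gene.start:gene.end]
        if gene.strand == "-":
            cds = (3 - cds)[::-1]
        return cds

    def gene_table(self) -> pd.DataFrame:
        """Gene coordinates relative to contigs, 1-based inclusive."""
        rows = []
        starts = np.array([s for _, s, _ in self.contig_bounds])
        for g in self.genes:
            ci = int(np.searchsorted(starts, g.start, side="right")) - 1
            cid, cs, _ = self.contig_bounds[ci]
            rows.append({"genome_id": self.genome_id, "gene_id": g.gene_id,
                         "contig_id": cid, "start": g.start - cs + 1,
                         "end": g.end - cs, "strand": g.strand,
                         "family": g.family})
        return pd.DataFrame(rows)


def make_core_pool(n_families: int, seed: int,
                   mean_codons: int = MEAN_GENE_CODONS) -> dict[str, np.ndarray]:
    """Ancestral CDS bodies for the shared core gene families."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC04E])
    chain = make_chain(0.50, tnf_seed=2)
    pool = {}
    for i in range(n_families):
        codons = max(MIN_GENE_CODONS,
                     int(rng.lognormal(math.log(mean_codons), 0.25)))
        pool[f"fam_{i + 1:04d}"] = _fix_stops(markov_codes(chain, 3 * codons, rng))
    return pool


def mutate_cds(body: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-mutate a CDS body (2:1 transition bias), repairing created stops."""
    out = _mutate_codes(body, rate, rng)
    return _fix_stops(out)


def _mutate_codes(codes: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        r = rng.random(hit.size)
        old = out[hit]
        new = np.where(r < 0.5, _TRANSITION[old],
                       np.where(r < 0.75, _TRANSVERSION_1[old],
                                _TRANSVERSION_2[old]))
        out[hit] = new
    return out


def _cut_contigs(build: GenomeBuild, rng: np.random.Generator,
                 median_len: int = 8000, sigma: float = 0.7,
                 min_len: int = 1000) -> None:
    """Cut the genome into contigs at intergenic positions (genes stay whole)."""
    length = build.codes.size
    gap_starts = np.array([s for s, _ in build.gaps])
    gap_ends = np.array([e for _, e in build.gaps])
    cuts = []
    pos = 0
    while True:
        target = pos + max(min_len, int(rng.lognormal(math.log(median_len), sigma)))
        if target >= length - min_len:
            break
        # snap to the nearest in-gap position at or after pos + min_len
        lo = pos + min_len
        cand = np.clip(target, gap_starts, gap_ends)
        cand = cand[(cand >= lo) & (cand < length - min_len)]
        if cand.size == 0:
            break
        cut = int(cand[np.argmin(np.abs(cand - target))])
        if cut <= pos:
            break
        cuts.append(cut)
        pos = cut
    bounds = []
    prev = 0
    for i, c in enumerate(cuts + [length]):
        bounds.append((f"{build.genome_id}_c{i:04d}", prev, c))
        prev = c
    build.contig_bounds = bounds


def generate_genome(model: GenomeModel, rng_seed: int,
                    core_pool: dict[str, np.ndarray] | None = None,
                    core_divergence: float = 0.06,
                    parent: GenomeBuild | None = None,
                    mean_gene_codons: int = MEAN_GENE_CODONS,
                    contig_median: int = 8000, contig_sigma: float = 0.7,
                    min_contig_len: int = 1000) -> GenomeBuild:
    """Realise one genome: sequence, gene layout, proteins and contigs.

    Bacterial genomes embed one mutated copy of every family in
    ``core_pool`` (at ``core_divergence`` per-base divergence from the
    ancestral sequence) scattered among de-novo private genes.  A strain
    model (``model.strain_of`` set) requires ``parent`` and is derived by
    mutating the parent's sequence; see :func:`strain_mutation_rate`.
    """
    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, 0x6E0])
    if model.strain_of is not None:
        if parent is None:
            raise ValueError(f"strain genome {model.genome_id} needs its parent build")
        return _derive_strain(model, parent, rng, contig_median, contig_sigma,
                              min_contig_len)

    mean_gene_nt = 3 * mean_gene_codons + 6
    if model.length < 3 * MIN_GENE_CODONS + 6 + 40:
        raise ValueError(f"genome length {model.length} too small to hold one gene")
    chain = make_chain(model.gc_target, model.tnf_seed)
    d = model.coding_density_target

    core_ids: list[str] = []
    core_slots: dict[int, str] = {}
    if core_pool and model.kind == "bacterium":
        core_ids = list(core_pool)
        n_est = int(model.length * d / mean_gene_nt)
        headroom = int(n_est * 0.93)
        if headroom < len(core_ids):
            raise ValueError(f"genome {model.genome_id} too small for "
                             f"{len(core_ids)} core families")
        slots = np.sort(rng.choice(headroom, size=len(core_ids), replace=False))
        core_slots = {int(s): fam for s, fam in zip(slots, core_ids)}

    mean_gap = max(20.0, mean_gene_nt * (1 - d) / d) if d > 0 else float(model.length)
    parts: list[np.ndarray] = []
    genes: list[Gene] = []
    gaps: list[tuple[int, int]] = []
    proteins: dict[str, str] = {}
    pos = 0
    gene_idx = 0
    while True:
        gap_len = 20 + int(rng.exponential(mean_gap - 20)) if d > 0 else model.length
        if gene_idx in core_slots:
            fam = core_slots[gene_idx]
            body = mutate_cds(core_pool[fam], core_divergence, rng)
        else:
            fam = f"priv_{model.genome_id}_{gene_idx:05d}"
            codons = max(MIN_GENE_CODONS,
                         int(rng.lognormal(math.log(mean_gene_codons), 0.25)))
            body = _fix_stops(markov_codes(chain, 3 * codons, rng))
        gene_nt = body.size + 6
        if pos + gap_len + gene_nt > model.length or d == 0:
            tail = model.length - pos
            if tail > 0:
                parts.append(markov_codes(chain, tail, rng))
                gaps.append((pos, pos + tail))
            break
        parts.append(markov_codes(chain, gap_len, rng))
        gaps.append((pos, pos + gap_len))
        pos += gap_len
        cds = np.concatenate([seq_to_codes("ATG"), body, seq_to_codes("TAA")])
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(cds if strand == "+" else (3 - cds)[::-1])
        gene_id = f"{model.genome_id}_g{gene_idx:05d}"
        genes.append(Gene(gene_id, fam, pos, pos + gene_nt, strand))
        proteins[gene_id] = _translate(np.concatenate([seq_to_codes("ATG"), body]))
        pos += gene_nt
        gene_idx += 1

    missing_core = set(core_ids) - {g.family for g in genes}
    if missing_core:
        raise ValueError(f"genome {model.genome_id} could not place core "
                         f"families {sorted(missing_core)[:5]}")

    build = GenomeBuild(model, np.concatenate(parts), genes, gaps,
                        proteins=proteins)
    _cut_contigs(build, rng, contig_median, contig_sigma, min_contig_len)
    return build


# ---------------------------------------------------------------------------
# strains

def _single_substitution_aa_change_fraction(parent: GenomeBuild,
                                            max_codons: int = 4000) -> float:
    """Mean probability that one biased substitution changes the amino acid."""
    alts = ((_TRANSITION, 0.5), (_TRANSVERSION_1, 0.25), (_TRANSVERSION_2, 0.25))
    total = 0.0
    n = 0
    for gene in parent.genes:
        cds = parent.gene_cds(gene)
        s = codes_to_seq(cds)
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            aa = _CODON_AA[codon]
            codes = seq_to_codes(codon)
            for p in range(3):
                for table, w in alts:
                    mut = codes.copy()
                    mut[p] = table[codes[p]]
                    if _CODON_AA[codes_to_seq(mut)] != aa:
                        total += w / 3.0
            n += 1
            if n >= max_codons:
                break
        if n >= max_codons:
            break
    return total / n


def strain_mutation_rate(parent: GenomeBuild, protein_identity: float) -> float:
    """Per-base substitution rate giving the target mean protein identity.

    Solved analytically: if a single substitution changes the encoded amino
    acid with probability f (averaged over the parent's codons under the
    2:1 transition-bias model), a per-base rate mu leaves a codon's amino
    acid intact with probability ~ (1 - mu*f)^3.
    """
    p_aa = 1.0 - protein_identity
    if p_aa <= 0:
        return 0.0
    f = _single_substitution_aa_change_fraction(parent)
    return (1.0 - (1.0 - p_aa) ** (1.0 / 3.0)) / f


def _derive_strain(model: GenomeModel, parent: GenomeBuild,
                   rng: np.random.Generator, contig_median: int,
                   contig_sigma: float, min_contig_len: int) -> GenomeBuild:
    rate = strain_mutation_rate(parent, model.protein_identity_to_parent)
    codes = _mutate_codes(parent.codes, rate, rng)
    genes = [Gene(f"{model.genome_id}_g{i:05d}", g.family, g.start, g.end, g.strand)
             for i, g in enumerate(parent.genes)]
    build = GenomeBuild(model, codes, genes, list(parent.gaps))
    build.proteins = {g.gene_id: _translate(build.gene_cds(g)[:-3]) for g in genes}
    _cut_contigs(build, rng, contig_median, contig_sigma, min_contig_len)
    return build


# ---------------------------------------------------------------------------
# depth, links, annotations

def simulate_depth(profile: CommunityProfile, contig_genome: dict[str, str],
                   seed: int | None = None, dispersion: float = 0.1
                   ) -> pd.DataFrame:
    """Per-contig mean depth in the two libraries.

    Depth is gamma-distributed around the genome's library mean with
    cv^2 = ``dispersion``; zero-abundance genomes get exactly zero depth.
    """
    rng = substream(profile.seed if seed is None else seed, "depth")
    known = {g.genome_id for g in profile.genomes}
    rows = []
    for cid, gid in contig_genome.items():
        if gid not in known:
            raise ValueError(f"contig {cid} maps to unknown genome {gid}")
        covs = []
        for ab in (profile.abundance_unmodified, profile.abundance_fractionated):
            m = ab[gid]
            covs.append(float(rng.gamma(1.0 / dispersion, dispersion * m))
                        if m > 0 else 0.0)
        rows.append({"contig_id": cid, "cov_A": covs[0], "cov_B": covs[1]})
    return pd.DataFrame(rows)


def simulate_links(contig_order: dict[str, list[str]], seed: int,
                   false_link_rate: float = 0.02, adjacent_mean: float = 8.0,
                   extra_rate: float = 0.2) -> pd.DataFrame:
    """Read-pair link counts between contigs.

    Adjacent contigs of the same genome are always linked (count
    ``2 + Poisson(adjacent_mean)``); a fraction ``extra_rate`` of random
    same-genome pairs get weak links; ``false_link_rate`` controls the
    expected fraction of spurious cross-genome links.
    """
    rng = substream(seed, "links")
    rows = []
    for gid, contigs in contig_order.items():
        for a, b in zip(contigs[:-1], contigs[1:]):
            rows.append({"contig_i": a, "contig_j": b,
                         "n_pairs": 2 + int(rng.poisson(adjacent_mean))})
        n_extra = int(len(contigs) * extra_rate) if len(contigs) >= 2 else 0
        for _ in range(n_extra):
            i, j = rng.choice(len(contigs), size=2, replace=False)
            rows.append({"contig_i": contigs[int(i)], "contig_j": contigs[int(j)],
                         "n_pairs": 1 + int(rng.poisson(2.0))})
    n_true = len(rows)
    all_contigs = [(gid, cid) for gid, cl in contig_order.items() for cid in cl]
    if false_link_rate > 0 and len(contig_order) > 1 and n_true:
        n_false = rng.binomial(n_true, false_link_rate / (1 - false_link_rate))
        made = 0
        while made < n_false:
            i, j = rng.choice(len(all_contigs), size=2, replace=False)
            if all_contigs[int(i)][0] == all_contigs[int(j)][0]:
                continue
            rows.append({"contig_i": all_contigs[int(i)][1],
                         "contig_j": all_contigs[int(j)][1],
                         "n_pairs": 1 + int(rng.poisson(1.0))})
            made += 1
    return pd.DataFrame(rows, columns=["contig_i", "contig_j", "n_pairs"])


def synthetic_go_dag() -> tuple[str, dict]:
    """A miniature GO-like ontology (OBO 1.2 text plus a term index).

    Around 40 biological_process terms in a 3-level hierarchy (with one
    diamond and one part_of edge) and a few molecular_function terms, enough
    to exercise true-path propagation and per-term enrichment.
    """
    bp_mid = {
        "metabolic process": ["carbohydrate metabolic process",
                              "amino acid metabolic process",
                              "nucleotide metabolic process",
                              "lipid metabolic process"],
        "transport": ["carbohydrate transport", "amino acid transport",
                      "ion transport", "protein transport",
                      "dicarboxylic acid transport"],
        "secretion": ["protein secretion", "toxin secretion"],
        "DNA metabolic process": ["DNA recombination", "DNA repair",
                                  "transposition", "DNA replication"],
        "biosynthetic process": ["glycosaminoglycan biosynthetic process",
                                 "vitamin biosynthetic process",
                                 "amino acid biosynthetic process",
                                 "polysaccharide biosynthetic process"],
        "signal transduction": ["two-component signaling", "quorum sensing",
                                "chemotaxis"],
        "stress response": ["oxidative stress response", "heat response"],
    }
    mf = ["transporter activity", "hydrolase activity", "transferase activity",
          "transposase activity"]
    terms: dict[str, dict] = {}
    idx = 1

    def add(name, namespace, parents, relationship=None):
        nonlocal idx
        tid = f"GO:9{idx:06d}"
        idx += 1
        terms[tid] = {"name": name, "namespace": namespace,
                      "is_a": list(parents), "part_of": list(relationship or [])}
        return tid

    bp_root = add("biological_process", "biological_process", [])
    mf_root = add("molecular_function", "molecular_function", [])
    leaf_ids = []
    by_name = {}
    for mid, leaves in bp_mid.items():
        mid_id = add(mid, "biological_process", [bp_root])
        by_name[mid] = mid_id
        for leaf in leaves:
            lid = add(leaf, "biological_process", [mid_id])
            by_name[leaf] = lid
            leaf_ids.append(lid)
    # diamond: glycosaminoglycan biosynthesis is also carbohydrate metabolism
    terms[by_name["glycosaminoglycan biosynthetic process"]]["is_a"].append(
        by_name["carbohydrate metabolic process"])
    # a part_of edge: chemotaxis part_of transport (toy relationship)
    terms[by_name["chemotaxis"]]["part_of"].append(by_name["transport"])
    for name in mf:
        lid = add(name, "molecular_function", [mf_root])
        by_name[name] = lid
        leaf_ids.append(lid)

    lines = ["format-version: 1.2", "ontology: holopipe-synthetic", ""]
    for tid, t in terms.items():
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {t['name']}")
        lines.append(f"namespace: {t['namespace']}")
        for p in t["is_a"]:
            lines.append(f"is_a: {p} ! {terms[p]['name']}")
        for p in t["part_of"]:
            lines.append(f"relationship: part_of {p} ! {terms[p]['name']}")
        lines.append("")
    obo = "\n".join(lines)
    index = {"terms": terms, "leaves": leaf_ids, "by_name": by_name,
             "bp_root": bp_root}
    return obo, index


DEFAULT_CATEGORIES = [
    "Carbohydrates", "Amino Acids and Derivatives", "Protein Metabolism",
    "DNA Metabolism", "Cofactors and Vitamins", "Membrane Transport",
    "Respiration", "Cell Wall and Capsule", "Stress Response",
    "Mobile Elements",
]


def emit_annotations(builds: list[GenomeBuild], seed: int, n_markers: int = 107,
                     marker_dropout: float = 0.0,
                     study_genomes: list[str] | None = None,
                     planted_terms: dict[str, float] | None = None,
                     planted_fold_default: float = 3.0,
                     mean_terms_per_gene: float = 1.5
                     ) -> dict[str, object]:
    """Marker, GO and functional-category annotation tables.

    Marker genes are the first ``n_markers`` core families, so every
    bacterial genome carries each marker exactly once (minus dropout) and
    eukaryote-kind genomes carry none.  GO terms are drawn per gene from a
    leaf-term frequency profile; terms in ``planted_terms`` are drawn at a
    multiplied rate in genes of ``study_genomes``, planting an enrichment
    with known effect size.
    """
    rng = substream(seed, "annotations")
    obo, go_index = synthetic_go_dag()
    study = set(study_genomes or [])
    leaves = go_index["leaves"]
    if planted_terms is None:
        planted_terms = {go_index["by_name"]["glycosaminoglycan biosynthetic process"]:
                         planted_fold_default}

    # background leaf-term weights: geometric-ish decay, fixed given the dag
    base_w = np.array([1.0 / (1.0 + 0.15 * i) for i in range(len(leaves))])
    base_w /= base_w.sum()
    study_w = base_w.copy()
    for term, fold in planted_terms.items():
        study_w[leaves.index(term)] *= fold
    study_w /= study_w.sum()

    marker_rows, go_rows, cat_rows = [], [], []
    marker_fams = {f"fam_{i + 1:04d}": f"SCG_{i + 1:04d}" for i in range(n_markers)}
    for build in builds:
        is_study = build.genome_id in study
        w = study_w if is_study else base_w
        cat_w = np.array([1.0 + 0.3 * float(rng.random()) for _ in DEFAULT_CATEGORIES])
        cat_w /= cat_w.sum()
        for gene in build.genes:
            if build.model.kind == "bacterium" and gene.family in marker_fams:
                if marker_dropout <= 0 or rng.random() >= marker_dropout:
                    marker_rows.append({"gene_id": gene.gene_id,
                                        "marker_id": marker_fams[gene.family]})
            k = int(rng.poisson(mean_terms_per_gene))
            if k > 0:
                picks = rng.choice(len(leaves), size=min(k, len(leaves)),
                                   replace=False, p=w)
                for t in picks:
                    go_rows.append({"gene_id": gene.gene_id,
                                    "go_id": leaves[int(t)]})
            cat = DEFAULT_CATEGORIES[int(rng.choice(len(DEFAULT_CATEGORIES),
                                                    p=cat_w))]
            cat_rows.append({"genome_id": build.genome_id,
                             "gene_id": gene.gene_id, "category": cat})
    return {
        "markers": pd.DataFrame(marker_rows, columns=["gene_id", "marker_id"]),
        "go": pd.DataFrame(go_rows, columns=["gene_id", "go_id"]),
        "categories": pd.DataFrame(cat_rows,
                                   columns=["genome_id", "gene_id", "category"]),
        "obo": obo,
        "go_index": go_index,
        "planted_terms": planted_terms,
    }


# ---------------------------------------------------------------------------
# whole community

@dataclass
class CommunityData:
    """Everything the synthetic community produced, in memory."""

    profile: CommunityProfile
    builds: list[GenomeBuild]
    depth: pd.DataFrame
    links: pd.DataFrame
    genes: pd.DataFrame
    markers: pd.DataFrame
    go: pd.DataFrame
    categories: pd.DataFrame
    obo: str
    truth: dict
    planted_terms: dict[str, float]

    def contigs(self) -> dict[str, str]:
        out = {}
        for b in self.builds:
            out.update(b.contigs())
        return out

    def proteins(self) -> dict[str, str]:
        out = {}
        for b in self.builds:
            for gid, aa in b.proteins.items():
                out[f"{b.genome_id}|{gid}"] = aa
        return out

    def contig_genome(self) -> dict[str, str]:
        return {cid: b.genome_id for b in self.builds
                for cid, _, _ in b.contig_bounds}

    def build(self, genome_id: str) -> GenomeBuild:
        for b in self.builds:
            if b.genome_id == genome_id:
                return b
        raise KeyError(genome_id)


def simulate_community(profile: CommunityProfile, n_core_families: int = 301,
                       n_markers: int = 107, core_divergence: float = 0.06,
                       false_link_rate: float = 0.02,
                       study_genomes: list[str] | None = None,
                       **annotation_kwargs) -> CommunityData:
    """Generate the full synthetic holobiont dataset from a profile.

    ``study_genomes`` defaults to the strain pair (a strain and its parent),
    mirroring a designated target taxon whose GO enrichment is planted.
    """
    seed = profile.seed
    core_pool = make_core_pool(n_core_families, seed)
    builds: list[GenomeBuild] = []
    by_id: dict[str, GenomeBuild] = {}
    # parents before strains
    ordered = sorted(profile.genomes, key=lambda g: g.strain_of is not None)
    for model in ordered:
        gseed = substream(seed, f"genome:{model.genome_id}").integers(2 ** 31)
        parent = by_id.get(model.strain_of) if model.strain_of else None
        b = generate_genome(model, int(gseed), core_pool=core_pool,
                            core_divergence=core_divergence, parent=parent)
        by_id[model.genome_id] = b
    builds = [by_id[g.genome_id] for g in profile.genomes]

    contig_genome = {cid: b.genome_id for b in builds
                     for cid, _, _ in b.contig_bounds}
    depth = simulate_depth(profile, contig_genome, seed)
    contig_order = {b.genome_id: [cid for cid, _, _ in b.contig_bounds]
                    for b in builds}
    links = simulate_links(contig_order, seed, false_link_rate=false_link_rate)

    if study_genomes is None:
        study_genomes = sorted({g.genome_id for g in profile.genomes
                                if g.strain_of is not None}
                               | {g.strain_of for g in profile.genomes
                                  if g.strain_of is not None})
    ann = emit_annotations(builds, seed, n_markers=n_markers,
                           study_genomes=study_genomes, **annotation_kwargs)
    genes = pd.concat([b.gene_table() for b in builds], ignore_index=True)
    truth = {
        "contig_genome": contig_genome,
        "genomes": {g.genome_id: {"kind": g.kind, "length": g.length,
                                  "gc_target": g.gc_target,
                                  "strain_of": g.strain_of}
                    for g in profile.genomes},
        "study_genomes": study_genomes,
        "core_families": sorted(core_pool),
        "marker_families": [f"fam_{i + 1:04d}" for i in range(n_markers)],
        "planted_terms": {k: float(v) for k, v in ann["planted_terms"].items()},
    }
    return CommunityData(profile, builds, depth, links, genes, ann["markers"],
                         ann["go"], ann["categories"], ann["obo"], truth,
                         ann["planted_terms"])


def write_community(data: CommunityData, outdir) -> dict[str, str]:
    """Write all community files to ``outdir``; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": out / "contigs.fasta",
        "depth": out / "depth.tsv",
        "links": out / "links.tsv",
        "proteins": out / "proteins.faa",
        "genes": out / "genes.tsv",
        "markers": out / "markers.tsv",
        "go": out / "go_annotations.tsv",
        "categories": out / "categories.tsv",
        "obo": out / "ontology.obo",
        "truth": out / "truth.json",
    }
    hio.write_fasta(data.contigs(), paths["contigs"])
    data.depth.to_csv(paths["depth"], sep="\t", index=False, float_format="%.4f")
    data.links.to_csv(paths["links"], sep="\t", index=False)
    hio.write_fasta(data.proteins(), paths["proteins"])
    data.genes.to_csv(paths["genes"], sep="\t", index=False)
    data.markers.to_csv(paths["markers"], sep="\t", index=False)
    data.go.to_csv(paths["go"], sep="\t", index=False)
    data.categories.to_csv(paths["categories"], sep="\t", index=False)
    paths["obo"].write_text(data.obo)
    hio.write_json(data.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
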