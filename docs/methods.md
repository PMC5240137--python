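# Methods

This note documents the models, parameters and design choices behind
`holopipe`, in the order the pipeline runs them.

## The synthetic holobiont community

The generator emulates the statistical structure a differential-coverage
binning analysis of a coral holobiont relies on; it does not simulate
reads, sequencing error, assembly or chimerism (contigs are error-free
genome fragments).

**Genome composition.** Each genome has an order-2 Markov chain over
bases. The chain is a fixed log-normal perturbation (sigma = 0.4 on the
log scale) of a GC-weighted base distribution, drawn from the genome's
`tnf_seed`; a scalar GC weight is solved by bisection on the chain's
stationary distribution so realized GC matches `gc_target` (tolerance
±0.02 is comfortably met). Distinct `tnf_seed`s make genomes separable in
canonical tetranucleotide space by construction; strains share the
parent's chain because they share its sequence.

**Genes and coding density.** Genes are stop-free codon runs sampled from
the genome's own chain (in-frame stops repaired), framed by ATG and TAA,
with log-normal lengths (median 280 codons, sigma 0.25, minimum 80).
Intergenic gaps are exponential with mean chosen so realized coding
density hits `coding_density_target` (bacteria ~0.9; host 0.25, alga 0.35
— eukaryote-kind genomes are capped at 0.4). Bacterial genomes embed one
copy of each shared **core gene family**: ancestral coding sequences
(default 301 families, matching the published core-set size this pipeline
is an analogue of) mutated per genome at 6% per-base divergence, scattered
uniformly among private genes. The first 107 families double as the
single-copy marker set (the marker count is configurable; published
single-copy marker sets are not enumerated in the source analysis, so 107
is a convention of this package, not an assertion).

**Strains.** A strain genome copies the parent's sequence and applies
point mutations with a 2:1 transition:transversion bias. The per-base rate
is solved analytically: with f the mean probability that one random
substitution changes the encoded amino acid (averaged over the parent's
codons under the biased mutation model, f ≈ 0.7), a rate mu leaves a
codon intact with probability ≈ (1 − mu·f)³, so mu =
(1 − identity^(1/3))/f. For the default target identity 0.974 this yields
mu ≈ 0.012 and realized mean core-protein identity within a few tenths of
a percent of target (97.36–97.4 across seeds). No tuning against test
outcomes is involved.

**Contigs.** Genome sequences are cut at log-normal spacings (median 8 kb,
sigma 0.7, minimum contig 1 kb), with each cut snapped to the nearest
intergenic gap so genes never span contigs. This mimics the highly
fragmented bins culture-independent assemblies produce.

**Depth.** Per-contig depth in each library is gamma-distributed with the
genome's library mean and squared coefficient of variation 0.1 — the
continuous analogue of a negative-binomial count with dispersion
0.1·mean (the gamma is the NB's mixing distribution); depth tables carry
float mean coverages, hence the continuous form. Zero-abundance genomes
get exactly zero depth.

**Links.** Adjacent contigs of a genome always share read-pair links
(2 + Poisson(8) pairs); 20% of contigs get weak longer-range intra-genome
links; cross-genome false links are injected at a configurable expected
fraction (default 0.02).

**Annotations.** GO terms are drawn per gene (Poisson mean 1.5 terms) from
a geometric-decay leaf-term profile over a ~40-term synthetic ontology
(three-level `biological_process` hierarchy with one diamond and one
`part_of` edge, plus a few `molecular_function` terms). Terms listed in
`planted_terms` are drawn at a multiplied rate (default 3×) in the
designated study genomes, planting an enrichment of known effect size.
Each gene also gets one subsystem-style functional category.

**Default community (~12.4 Mb).** Host 2.0 Mb (GC 0.39), alga 1.0 Mb
(GC 0.50), strain pair 2 × 2.2 Mb (GC 0.48, protein identity 0.974), and
three further bacteria of 2.0/1.6/1.4 Mb at GC 0.55/0.44/0.53 — four
compositionally unrelated bacterial lineages in total. Abundances
(unmodified → fractionated): host 120 → 6, alga 70 → 3, strain pair
12 → 48 and 13 → 52 (overlapping clouds, so the pair co-bins), and
50 → 12, 12 → 12, 45 → 45 for the others. These sizes are scaled-down
analogues of published culture-independent *Endozoicomonas* assemblies
(2.3–6.3 Mb); the total is sized so a full run (generation through
phylogeny and enrichment) completes in about half a minute on one CPU.

**What passing on this generator shows — and what it does not.** The
synthetic community realizes exactly the assumptions the method states
(genome-specific composition, differential abundance, complete marker
complements, planted enrichments). Success here demonstrates the
algorithms implement their definitions and recover planted truth; it does
not demonstrate robustness to real-data pathologies such as assembly
chimeras, repeat-collapsed contigs, uneven within-genome coverage (e.g.
from whole-genome amplification), horizontally transferred regions, or
incomplete marker annotation.

## Per-contig features

* **TNF**: every 4-mer window (step 1), windows containing `N` skipped,
  reverse-complement pairs pooled under the lexicographically smaller key
  (136 canonical 4-mers), normalised to frequencies. The canonical
  convention halves dimensionality and removes strand effects; it is this
  package's declared convention.
* **GC**: (G+C)/(A+C+G+T), `N` excluded.
* **Coding density**: union of ≥ `min_orf_codons` stop-free codon runs
  over all six frames, divided by length — a stop-to-stop proxy for gene
  density that needs no start-codon model. Default
  `min_orf_codons = 100`: at 60 codons the expected fraction of a random
  sequence covered by qualifying runs is ~0.75 (stop probability 3/64 per
  codon; ~23% of codons sit in ≥60-codon runs per frame, ~0.75 after the
  six-frame union), which would erase the prokaryote/eukaryote contrast;
  at 100 codons random sequence scores ~0.29 while gene-dense bacterial
  contigs score ~0.95, giving a ~0.5 median gap.

## Binning

Features (default: log10 depth in both libraries with pseudo-depth 0.01,
coding density, and the top 3 principal components of TNF) are centred and
scaled to unit variance; PCA component signs are fixed by making the
largest-magnitude loading positive. Clustering is DBSCAN with eps = 0.5
and min_pts = 5 in that standardized space — an automated, parameterised
stand-in for interactive coverage-plot polygon selection. The defaults are
calibrated to the default community's contig density (~1300 contigs);
DBSCAN densities do not transfer to much smaller contig sets, where a
wider eps is appropriate (see `examples/03`). Contigs under 1 kb are
excluded (composition features are unstable below that). Determinism:
contigs are processed in lexicographic id order; border points join the
first core cluster in that order.

Refinement: unbinned contigs whose pooled link count reaches `min_links`
(default 3) for exactly one bin join it, iterated to a fixed point;
contigs reaching the threshold for two or more bins are ambiguous and stay
out. The contaminant purge removes eukaryote-labelled contigs from
bacterial bins (identified by marker-gene presence), keeping — with a
warning — any labelled contig that itself carries bacterial markers.

Evaluation is length-weighted per bin: precision = majority-genome length
/ binned length; recall = that length / the genome's total contig length.
On the default community the strain pair is deliberately unresolvable
(overlapping coverage, shared composition), so evaluation merges the pair
into one truth label; the pair's presence is then asserted through its
marker signature (completeness 100, contamination 100, heterogeneity 2)
rather than through a per-strain split no method of this class could
achieve.

## Marker scoring

A flat single-copy marker set with explicit formulas (see README) replaces
lineage-specific collocated marker machinery: the upstream analysis uses
marker scoring only to report three scalar quality numbers, and the flat
form is exactly testable (completeness of a p-thinned bin is binomially
distributed with mean 100p). "Heterogeneity" is defined as the maximum
marker copy number — the definition that reproduces the published value 2
for a two-strain bin; percentage-based strain-heterogeneity variants are
not replicated.

## Pan-genome and phylogeny

The orthoMCL recipe is followed with two desk-scale substitutions, both
deliberate: the BLAST similarity stage is replaced by exact global
alignment (Needleman–Wunsch, BLOSUM62, gap open −11 / extend −1 with the
first gap residue costing the open score), and edges require ≥ 50%
identity (denominator: alignment columns, including gap columns — the
published 97.4% figure's denominator convention is not stated, so this
package declares its own) plus ≥ 0.5 shorter-sequence coverage. A
shared-8-mer prescreen skips alignments between sequences having no exact
8-mer in common; at the 50% identity threshold such pairs cannot form
edges, so the prescreen changes no result, only runtime (it can be
disabled with `prescreen_k=None`). MCL runs per connected component
(exact, since MCL never merges components) with self-loops, column
normalisation, expansion/inflation iterations to a 1e-6 fixed point, and
inflation 1.5 (the orthoMCL convention).

The multiple aligner is center-star (center = minimal summed pairwise
distance; pairwise alignments merged on the center's coordinates) — a
bounded, deterministic substitute for progressive MSA; the strict
gap-column filter (drop any column with a gap, Gblocks-like) feeds the
concatenation. Distances are Poisson-corrected protein distances
d = −ln(1−p) with p capped at 0.95 (warned); trees are Saitou–Nei
neighbor joining (exact on additive matrices, which the tests verify on
random additive trees); support is the bipartition frequency over
column-resampling bootstrap replicates. NJ with Poisson correction
replaces maximum-likelihood inference: at the divergences the synthetic
core genes span, topology is model-insensitive and NJ is fully
specifiable and testable. The pipeline default is 100 bootstrap
replicates (sized to the run budget; the conventional 1000 is a parameter
away).

## GO enrichment

Classic per-term one-sided Fisher tests (hypergeometric upper tail,
computed by scipy in log space), after true-path propagation over an OBO
subset (`is_a` plus optional `part_of`; obsolete terms dropped; cycles and
dangling parents are errors). Term-decorrelation schemes (topGO's
"weight01"/"elim") are intentionally not replicated — the analysis this
package mirrors reports plain Fisher p-values. Raw p-values are reported;
a Benjamini–Hochberg column is available but off by default, matching the
published table's raw-p layout. The gene universe is all background genes
with ≥ 1 propagated annotation. The published comparison table's absolute
background sizes are not printed; only its study-set fraction is
recoverable from the largest row, so Expected-count arithmetic uses that
implied fraction at an integer scale (×100), and the all-in-study row's p
is reproduced in the large-background limit (p → fraction^k for K = k).

## Numerical and degenerate-input conventions

* Internal coordinates 0-based half-open; emitted tables 1-based
  inclusive; all tabular outputs are TSV with header rows.
* All-`N` sequences: GC is an error; TNF returns an all-zero vector with
  a warning; N-containing windows/codons are skipped rather than
  ambiguity-expanded.
* Zero-variance features are dropped with a warning before clustering;
  zero coverage stays finite via the pseudo-depth.
* Proteins: a single trailing `*` is stripped before quality checks; kept
  sequences are passed through unchanged (the filter is idempotent);
  alignment accepts the 20 standard residues plus B, Z, X and `*`.
* Single pipeline seed; per-stage substreams derived by CRC32 of the
  stage name, so stages are statistically independent and individually
  reproducible.

## Known limitations

Beyond the generator caveats above: the binning defaults are density
parameters and need rescaling for very small or very large contig sets;
center-star alignment is a 2-approximation and can differ from progressive
MSAs in gappy regions (the strict column filter removes most of the
difference); the marker set is flat (no lineage-specific selection); the
OBO parser handles the stated subset only (no OBO 1.4 semantics, GO
slims, or cross-products); and enrichment p-values are raw, so downstream
users comparing many terms should enable the BH column.
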