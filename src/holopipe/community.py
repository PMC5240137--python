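"""Community models for the synthetic holobiont generator.

A synthetic holobiont community emulates the statistical structure of a
coral metagenome sequenced twice — once unmodified (dominated by host and
algal-symbiont DNA) and once size-fractionated (bacterially enriched) — so
that differential-coverage binning has a signal to work with.  Each genome
is described by a :class:`GenomeModel`; the community plus its two
abundance profiles is a :class:`CommunityProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass

KINDS = ("host", "alga", "bacterium")
EUKARYOTE_KINDS = ("host", "alga")


@dataclass
class GenomeModel:
    """Parameters of one synthetic genome.

    ``tnf_seed`` drives a genome-specific order-2 Markov chain over bases,
    making genomes tetranucleotide-separable by construction.  A strain
    genome (``strain_of`` set) is derived by mutating its parent's sequence
    at a per-base rate calibrated so the mean protein identity to the
    parent's orthologs is ``protein_identity_to_parent``.
    """

    genome_id: str
    kind: str
    length: int
    gc_target: float
    tnf_seed: int
    coding_density_target: float
    strain_of: str | None = None
    protein_identity_to_parent: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown genome kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if not 0.0 <= self.coding_density_target <= 1.0:
            raise ValueError("coding_density_target must be in [0, 1]")
        if self.kind in EUKARYOTE_KINDS and self.coding_density_target > 0.4:
            raise ValueError("eukaryote-kind genomes must have coding density <= 0.4")
        if not 0.0 <= self.protein_identity_to_parent <= 1.0:
            raise ValueError("protein_identity_to_parent must be in [0, 1]")

    @property
    def is_eukaryote(self) -> bool:
        return self.kind in EUKARYOTE_KINDS


@dataclass
class CommunityProfile:
    """A set of genomes plus their mean coverage in the two metagenomes."""

    genomes: list[GenomeModel]
    abundance_unmodified: dict[str, float]
    abundance_fractionated: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids")
        for g in self.genomes:
            if g.strain_of is not None and g.strain_of not in ids:
                raise ValueError(f"strain {g.genome_id} references unknown "
                                 f"parent {g.strain_of}")
        for name, ab in (("unmodified", self.abundance_unmodified),
                         ("fractionated", self.abundance_fractionated)):
            missing = set(ids) - set(ab)
            if missing:
                raise ValueError(f"{name} abundances missing for {sorted(missing)}")
            if any(v < 0 for v in ab.values()):
                raise ValueError(f"negative {name} abundance")
        if not self._has_differential():
            raise ValueError("no bacterium has a fractionated/unmodified coverage "
                             "ratio differing from the host's by a factor >= 2; "
                             "differential-coverage binning needs this contrast")

    def _has_differential(self) -> bool:
        hosts = [g for g in self.genomes if g.kind == "host"]
        bacts = [g for g in self.genomes if g.kind == "bacterium"]
        if not hosts or not bacts:
            return True  # nothing to contrast against
        eps = 1e-9
        for h in hosts:
            rh = (self.abundance_fractionated[h.genome_id] + eps) / \
                 (self.abundance_unmodified[h.genome_id] + eps)
            for b in bacts:
                rb = (self.abundance_fractionated[b.genome_id] + eps) / \
                     (self.abundance_unmodified[b.genome_id] + eps)
                if rb / rh >= 2.0 or rh / rb >= 2.0:
                    return True
        return False

    def by_id(self, genome_id: str) -> GenomeModel:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    @property
    def bacteria(self) -> list[GenomeModel]:
        return [g for g in self.genomes if g.kind == "bacterium"]


def default_community(seed: int = 0) -> CommunityProfile:
    """The default synthetic holobiont (~12.4 Mb total).

    One gene-sparse host genome, one algal-symbiont genome, four unrelated
    bacteria of distinct tetranucleotide composition, and one bacterial
    strain pair at 97.4% mean protein identity that shares an abundance
    profile (its contig clouds overlap in coverage space, so the pair is
    expected to co-bin).  The fractionated library enriches bacteria and
    depletes host/algal DNA.
    """
    genomes = [
        GenomeModel("host", "host", 2_000_000, 0.39, tnf_seed=11,
                    coding_density_target=0.25),
        GenomeModel("alga", "alga", 1_000_000, 0.50, tnf_seed=23,
                    coding_density_target=0.35),
        GenomeModel("endo_a", "bacterium", 2_200_000, 0.48, tnf_seed=37,
                    coding_density_target=0.90),
        GenomeModel("endo_b", "bacterium", 2_200_000, 0.48, tnf_seed=37,
                    coding_density_target=0.90, strain_of="endo_a",
                    protein_identity_to_parent=0.974),
        GenomeModel("bact_c", "bacterium", 2_000_000, 0.55, tnf_seed=53,
                    coding_density_target=0.90),
        GenomeModel("bact_d", "bacterium", 1_600_000, 0.44, tnf_seed=71,
                    coding_density_target=0.88),
        GenomeModel("bact_e", "bacterium", 1_400_000, 0.53, tnf_seed=89,
                    coding_density_target=0.92),
    ]
    abundance_unmodified = {
        "host": 120.0, "alga": 70.0,
        "endo_a": 12.0, "endo_b": 13.0,
        "bact_c": 50.0, "bact_d": 12.0, "bact_e": 45.0,
    }
    abundance_fractionated = {
        "host": 6.0, "alga": 3.0,
        "endo_a": 48.0, "endo_b": 52.0,
        "bact_c": 12.0, "bact_d": 12.0, "bact_e": 45.0,
    }
    return CommunityProfile(genomes, abundance_unmodified,
                            abundance_fractionated, seed=seed)
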