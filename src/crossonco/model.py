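"""Shared data model for cross-species tumor copy-number analysis.

Conventions
-----------
Coordinates are 1-based and inclusive, matching the SEG / annotation file
formats this package reads and writes.  Interval arithmetic (midpoint
containment, span computation) goes through the helper properties below so
the convention lives in one place.

Copy-number values are mean log2 ratios of a tumor segment relative to the
sample's *baseline ploidy* (3N for the near-triploid fish tumors, 2N for
human), so 0 means "at baseline", not "diploid".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Species",
    "Biotype",
    "GenotypeGroup",
    "GeneRecord",
    "Segment",
    "SampleProfile",
    "CohortMeta",
    "ChromothripsisParams",
    "PipelineConfig",
    "FISH_CHROMOSOMES",
    "HUMAN_CHROMOSOMES",
    "assign_ordinals",
    "genes_by_chromosome",
]


class Species(str, Enum):
    HUMAN = "human"
    FISH = "fish"


class Biotype(str, Enum):
    PROTEIN_CODING = "protein_coding"
    MIRNA = "miRNA"


class GenotypeGroup(str, Enum):
    """Tumor-initiating genotype of the animal/patient a sample came from."""

    RP_DIPLOID = "rp_diploid"
    TP53_DIPLOID = "tp53_diploid"
    TP53_TRIPLOID = "tp53_triploid"
    HUMAN_NF1 = "human_NF1"


#: Assembled zebrafish chromosomes 1-25.
FISH_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 26))
#: Human chromosomes 1-22 and X (no Y; the annotation universe excludes it).
HUMAN_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus in one species.

    ``ordinal`` is the 0-based rank of the gene among all genes on its
    chromosome, sorted by start coordinate (ties broken by gene id).  All
    synteny logic operates on ordinals rather than base pairs.
    """

    gene_id: str
    species: Species
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    biotype: Biotype = Biotype.PROTEIN_CODING
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Single reference position used to assign a gene to a segment."""
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number stretch of a sample's genome."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    value: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"segment {self.chromosome}:{self.start_bp}-{self.end_bp}: "
                "start > end"
            )
        if self.n_markers < 1:
            raise ValueError("segment must have at least one marker")

    def contains(self, position: int) -> bool:
        return self.start_bp <= position <= self.end_bp

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SampleProfile:
    """Ordered, non-overlapping copy-number segments for one tumor."""

    sample_id: str
    genotype_group: GenotypeGroup
    baseline_ploidy: int
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_ploidy not in (2, 3):
            raise ValueError(
                f"sample {self.sample_id}: baseline ploidy must be 2 or 3"
            )

    def segments_on(self, chromosome: str) -> list[Segment]:
        return [s for s in self.segments if s.chromosome == chromosome]

    def validate(self) -> None:
        """Check the sorted / non-overlapping invariant per chromosome."""
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in by_chrom.items():
            ordered = sorted(segs, key=lambda s: s.start_bp)
            for a, b in zip(ordered, ordered[1:]):
                if b.start_bp <= a.end_bp:
                    raise ValueError(
                        f"sample {self.sample_id} chr{chrom}: segments "
                        f"{a.start_bp}-{a.end_bp} and {b.start_bp}-{b.end_bp} overlap"
                    )


@dataclass
class CohortMeta:
    """Expected shape of a tumor cohort: species, group sizes, chromosomes."""

    species: Species
    group_counts: dict[GenotypeGroup, int]
    chromosomes: tuple[str, ...]

    @classmethod
    def fish_default(cls) -> "CohortMeta":
        return cls(
            species=Species.FISH,
            group_counts={
                GenotypeGroup.RP_DIPLOID: 53,
                GenotypeGroup.TP53_DIPLOID: 49,
                GenotypeGroup.TP53_TRIPLOID: 45,
            },
            chromosomes=FISH_CHROMOSOMES,
        )

    @classmethod
    def human_default(cls) -> "CohortMeta":
        return cls(
            species=Species.HUMAN,
            group_counts={GenotypeGroup.HUMAN_NF1: 23},
            chromosomes=HUMAN_CHROMOSOMES,
        )

    @property
    def n_samples(self) -> int:
        return sum(self.group_counts.values())


@dataclass
class ChromothripsisParams:
    """Thresholds for the copy-number-oscillation chromothripsis signature.

    ``delta`` is the log2-ratio band around 0 treated as "neutral";
    ``min_switches`` (K) is the minimum number of adjacent state changes in
    the oscillating window; ``max_states`` caps the number of distinct
    states inside the window (the signature is toggling between two or
    three states, not a staircase); ``min_span`` is the minimum fraction of
    the chromosome the window must cover.
    """

    delta: float = 0.2
    min_switches: int = 6
    max_states: int = 3
    min_span: float = 0.3


@dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages.

    ``amplitude_cutoff`` (theta) is the |log2 ratio| above which a gene
    counts as altered in a sample; ``q_cutoff_fish`` / ``q_cutoff_human``
    are the per-species recurrence significance cutoffs (the human cohort
    is small, so its cutoff is intentionally more permissive);
    ``focal_max_span_bp`` separates focal from chromosome-scale regions;
    ``synteny_window`` (W) is the ordinal window defining conserved
    synteny.
    """

    amplitude_cutoff: float = 0.2
    q_cutoff_fish: float = 0.25
    q_cutoff_human: float = 10 ** -0.2
    focal_max_span_bp: int = 10_000_000
    synteny_window: int = 100
    permutations: int = 200
    rng_seed: int = 0
    chromothripsis: ChromothripsisParams = field(default_factory=ChromothripsisParams)

    def __post_init__(self) -> None:
        if self.amplitude_cutoff <= 0:
            raise ValueError("amplitude_cutoff must be > 0")
        for q in (self.q_cutoff_fish, self.q_cutoff_human):
            if not (0 < q <= 1):
                raise ValueError("q cutoffs must be in (0, 1]")
        if self.synteny_window < 1:
            raise ValueError("synteny_window must be >= 1")
        if self.permutations < 100:
            raise ValueError("permutations must be >= 100")

    def q_cutoff(self, species: Species) -> float:
        return self.q_cutoff_fish if species == Species.FISH else self.q_cutoff_human


def assign_ordinals(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Return genes with per-chromosome ordinals assigned.

    Genes are ranked by start coordinate within each chromosome, ties broken
    by gene id, yielding a dense 0..n-1 sequence per chromosome.  Output is
    sorted by (chromosome, ordinal).
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: list[GeneRecord] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        ranked = sorted(by_chrom[chrom], key=lambda g: (g.start_bp, g.gene_id))
        out.extend(replace(g, ordinal=i) for i, g in enumerate(ranked))
    return out


def genes_by_chromosome(genes: Sequence[GeneRecord]) -> dict[str, list[GeneRecord]]:
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: g.ordinal)
    return by_chrom


def _chrom_key(chrom: str):
    """Sort numeric chromosomes numerically, then X and other names."""
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)
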