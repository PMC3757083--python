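"""Synthetic genome pairs and tumor cohorts with known ground truth.

The generator emulates the study design this package is built for:

* two genomes related by one whole-genome duplication on the fish lineage
  (so a human gene can have up to two fish paralogs) followed by block-wise
  rearrangement with small conserved blocks (geometric sizes, mean ~5
  genes, so ~90% of blocks hold <= 10 genes);
* a near-triploid fish tumor cohort of three genotype groups
  (53 + 49 + 45 = 147 samples) and a small diploid human cohort
  (23 samples), with planted recurrent whole-chromosome gains/losses,
  focal events centered on planted driver genes, random passenger
  segments, chromothripsis-like state oscillations, and Gaussian segment
  noise;
* a similarity table standing in for protein similarity-search scores, and
  miRNA annotations whose identifier numeric cores define cross-species
  families.

Everything is deterministic given ``SimulationConfig.rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import write_genes, write_seg, write_similarity
from .model import (
    Biotype,
    GeneRecord,
    GenotypeGroup,
    SampleProfile,
    Segment,
    Species,
    assign_ordinals,
    genes_by_chromosome,
)
from .recurrence import RecurrentRegion

__all__ = [
    "SimilarityParams",
    "SimulationConfig",
    "PlantedFocal",
    "TruthSet",
    "simulate_genomes",
    "simulate_cohort",
    "simulate_study",
    "emit_fixtures",
    "regions_from_truth",
]

# One-copy log2 shifts on each baseline: 3N->4N, 3N->2N, 2N->3N, 2N->1N.
FISH_GAIN_AMP = math.log2(4 / 3)
FISH_LOSS_AMP = math.log2(2 / 3)
HUMAN_GAIN_AMP = math.log2(3 / 2)
HUMAN_LOSS_AMP = math.log2(1 / 2)


@dataclass
class SimilarityParams:
    """Score model for the synthetic similarity table.

    True ortholog pairs score ~Normal(ortholog_score_mean, ortholog_score_sd);
    retained second fish paralogs get the same draw with the mean multiplied
    by ``paralog_penalty`` (slightly weaker hits, as expected after
    post-duplication divergence); each fish gene additionally picks up
    ~Poisson(background_rate) spurious low-scoring human partners.
    """

    ortholog_score_mean: float = 200.0
    ortholog_score_sd: float = 8.0
    paralog_penalty: float = 0.96
    background_rate: float = 0.5
    background_score_mean: float = 80.0
    background_score_sd: float = 15.0
    #: fraction of ancestral genes with no usable similarity evidence at all
    #: (orphans / failed assignments); their pairs appear neither in the
    #: similarity table nor in the truth set, leaving roughly two-thirds of
    #: human genes represented in the correspondence table
    missing_prob: float = 0.32


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-scale defaults."""

    n_ancestral_genes: int = 3400
    n_human_chroms: int = 23
    n_fish_chroms: int = 25
    wgd_retention_prob: float = 0.5
    block_size_mean: float = 5.0
    similarity: SimilarityParams = field(default_factory=SimilarityParams)

    # gene layout (bp)
    human_gene_spacing_bp: int = 120_000
    fish_gene_spacing_bp: int = 100_000
    gene_length_bp: int = 20_000

    # cohort sizes
    n_rp_diploid: int = 53
    n_tp53_diploid: int = 49
    n_tp53_triploid: int = 45
    n_human_samples: int = 23

    # planted recurrent events
    n_fish_gain_chroms: int = 9
    n_fish_loss_chroms: int = 6
    n_human_gain_chroms: int = 5
    n_human_loss_chroms: int = 13
    n_fish_focal_gains: int = 14
    n_fish_focal_losses: int = 3
    n_human_focal_gains: int = 13
    n_human_focal_losses: int = 7
    large_event_prob: float = 0.6
    focal_event_prob: float = 0.3
    focal_width_mean_bp: int = 2_000_000
    focal_width_sd_bp: int = 400_000
    focal_gain_amp: float = 1.0
    focal_loss_amp: float = -1.0

    # noise processes
    passenger_rate: float = 6.0
    passenger_min_frac: float = 0.02
    passenger_max_frac: float = 0.3
    chromothripsis_rate_fish: float = 0.013
    chromothripsis_rate_human: float = 0.083
    noise_sd: float = 0.05

    # miRNA families
    n_mirna_families: int = 89
    n_concordant_gain_families: int = 8
    n_concordant_loss_families: int = 9

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.wgd_retention_prob, self.large_event_prob, self.focal_event_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.block_size_mean < 1:
            raise ValueError("block_size_mean must be >= 1")
        if min(self.n_rp_diploid, self.n_tp53_diploid, self.n_tp53_triploid,
               self.n_human_samples) < 0:
            raise ValueError("cohort sizes must be >= 0")

    def spacing(self, species: Species) -> int:
        return (
            self.fish_gene_spacing_bp
            if species == Species.FISH
            else self.human_gene_spacing_bp
        )


@dataclass(frozen=True)
class PlantedFocal:
    """A focal driver locus planted in one species."""

    species: Species
    polarity: str  # "gain" | "loss"
    chromosome: str
    gene_id: str
    center_bp: int


@dataclass
class TruthSet:
    """Ground truth emitted by the generator, consumed by recovery tests."""

    ortholog_pairs: dict[str, str] = field(default_factory=dict)  # fish -> human
    gain_chromosomes: dict[str, list[str]] = field(default_factory=dict)
    loss_chromosomes: dict[str, list[str]] = field(default_factory=dict)
    focal_drivers: list[PlantedFocal] = field(default_factory=list)
    chromothripsis_events: list[tuple[str, str, str]] = field(default_factory=list)
    mirna_gain_families: list[str] = field(default_factory=list)
    mirna_loss_families: list[str] = field(default_factory=list)

    def focals(self, species: Species, polarity: str | None = None) -> list[PlantedFocal]:
        return [
            f
            for f in self.focal_drivers
            if f.species == species and (polarity is None or f.polarity == polarity)
        ]


# ---------------------------------------------------------------------------
# genome simulation


def _geometric_blocks(n: int, mean: float, rng: np.random.Generator) -> list[int]:
    """Partition n genes into consecutive blocks with geometric sizes."""
    if not math.isfinite(mean):
        return [n] if n else []
    p = 1.0 / mean
    sizes: list[int] = []
    total = 0
    while total < n:
        size = min(int(rng.geometric(p)), n - total)
        sizes.append(size)
        total += size
    return sizes


def _scatter_blocks(
    items: list[list[str]], n_chroms: int, rng: np.random.Generator
) -> list[list[str]]:
    """Shuffle blocks and deal them onto chromosomes, balancing gene counts."""
    order = rng.permutation(len(items))
    chroms: list[list[str]] = [[] for _ in range(n_chroms)]
    counts = np.zeros(n_chroms, dtype=int)
    for idx in order:
        target = int(np.argmin(counts))
        chroms[target].extend(items[idx])
        counts[target] += len(items[idx])
    return chroms


def _lay_out(
    chrom_gene_ids: list[list[str]],
    species: Species,
    config: SimulationConfig,
) -> list[GeneRecord]:
    spacing, length = config.spacing(species), config.gene_length_bp
    genes: list[GeneRecord] = []
    for c, ids in enumerate(chrom_gene_ids, start=1):
        chrom = str(c) if not (species == Species.HUMAN and c == 23) else "X"
        for k, gid in enumerate(ids):
            start = k * spacing + 1
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    species=species,
                    chromosome=chrom,
                    start_bp=start,
                    end_bp=start + length - 1,
                    strand="+",
                    biotype=Biotype.PROTEIN_CODING,
                )
            )
    return genes


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], list[GeneRecord], pd.DataFrame, TruthSet]:
    """Generate the human/fish genome pair, similarity table and truth set.

    Returns ``(human_genes, fish_genes, similarity, truth)``.  The truth
    set already fixes which chromosomes will be recurrently altered and
    where the focal drivers sit, so that the miRNA annotation can be laid
    out consistently and the cohort simulator can plant matching events.
    """
    n = config.n_ancestral_genes
    if n < max(config.n_human_chroms, config.n_fish_chroms):
        raise ValueError("n_ancestral_genes must be >= the chromosome count")
    rng = np.random.default_rng([config.rng_seed, 1])
    truth = TruthSet()

    human_ids = [f"HG{i:05d}" for i in range(n)]
    # Human genome: ancestral order cut into blocks, blocks scattered.
    sizes = _geometric_blocks(n, config.block_size_mean, rng)
    blocks, pos = [], 0
    for s in sizes:
        blocks.append(human_ids[pos : pos + s])
        pos += s
    human_chrom_ids = _scatter_blocks(blocks, config.n_human_chroms, rng)

    # Fish genome: WGD gives copy A of every ancestral gene plus copy B of a
    # retained subset; each sub-genome is cut into blocks independently and
    # all blocks are scattered over the fish chromosomes.
    retained = rng.random(n) < config.wgd_retention_prob
    masked = rng.random(n) < config.similarity.missing_prob
    copy_a = [f"FG{i:05d}A" for i in range(n)]
    copy_b = [f"FG{i:05d}B" for i in range(n) if retained[i]]
    for i in range(n):
        if masked[i]:
            continue  # orphan: no similarity evidence, excluded from truth
        truth.ortholog_pairs[f"FG{i:05d}A"] = human_ids[i]
        if retained[i]:
            truth.ortholog_pairs[f"FG{i:05d}B"] = human_ids[i]
    fish_blocks: list[list[str]] = []
    for ids in (copy_a, copy_b):
        pos = 0
        for s in _geometric_blocks(len(ids), config.block_size_mean, rng):
            fish_blocks.append(ids[pos : pos + s])
            pos += s
    fish_chrom_ids = _scatter_blocks(fish_blocks, config.n_fish_chroms, rng)

    human_genes = _lay_out(human_chrom_ids, Species.HUMAN, config)
    fish_genes = _lay_out(fish_chrom_ids, Species.FISH, config)

    # Planted recurrent chromosomes.
    truth.gain_chromosomes = {}
    truth.loss_chromosomes = {}
    for species, genes, n_gain, n_loss in (
        (Species.FISH, fish_genes, config.n_fish_gain_chroms, config.n_fish_loss_chroms),
        (Species.HUMAN, human_genes, config.n_human_gain_chroms, config.n_human_loss_chroms),
    ):
        chroms = sorted({g.chromosome for g in genes}, key=_chrom_sort)
        if n_gain + n_loss > len(chroms):
            raise ValueError("more planted chromosomes than chromosomes")
        picked = rng.choice(len(chroms), size=n_gain + n_loss, replace=False)
        truth.gain_chromosomes[species.value] = sorted(
            (chroms[i] for i in picked[:n_gain]), key=_chrom_sort
        )
        truth.loss_chromosomes[species.value] = sorted(
            (chroms[i] for i in picked[n_gain:]), key=_chrom_sort
        )

    _plant_focals(truth, human_genes, fish_genes, config, rng)
    mirna_human, mirna_fish = _plant_mirnas(truth, human_genes, fish_genes, config, rng)
    human_genes = assign_ordinals(human_genes + mirna_human)
    fish_genes = assign_ordinals(fish_genes + mirna_fish)

    similarity = _simulate_similarity(truth, human_ids, config, rng)
    return human_genes, fish_genes, similarity, truth


def _chrom_sort(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _chrom_span(genes: Sequence[GeneRecord], spacing: int) -> int:
    n_slots = max(g.start_bp for g in genes) // spacing + 1
    return n_slots * spacing


def _plant_focals(
    truth: TruthSet,
    human_genes: list[GeneRecord],
    fish_genes: list[GeneRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Choose focal driver loci: a few ride on altered chromosomes, the rest
    sit on neutral chromosomes; centers are kept well separated."""
    for species, genes, n_gain, n_loss in (
        (Species.FISH, fish_genes, config.n_fish_focal_gains, config.n_fish_focal_losses),
        (Species.HUMAN, human_genes, config.n_human_focal_gains, config.n_human_focal_losses),
    ):
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        gain_chroms = truth.gain_chromosomes[species.value]
        loss_chroms = truth.loss_chromosomes[species.value]
        all_chroms = sorted(by_chrom, key=_chrom_sort)
        # host chromosome sequence: 2 ride-on-gain, 1 on a lost chromosome
        # (a focal gain inside an under-represented chromosome), remainder
        # cycles over all chromosomes so hosts stay spread out.
        gain_hosts = [
            gain_chroms[i % len(gain_chroms)] for i in range(min(2, n_gain))
        ] if gain_chroms else []
        if n_gain > 2 and loss_chroms:
            gain_hosts.append(loss_chroms[0])
        while len(gain_hosts) < n_gain:
            gain_hosts.append(all_chroms[len(gain_hosts) % len(all_chroms)])
        loss_hosts = [
            all_chroms[(2 * i + 1) % len(all_chroms)] for i in range(n_loss)
        ]
        taken: dict[str, list[int]] = {}
        spacing = config.spacing(species)
        # widths are clipped at twice the mean, so this keeps windows disjoint
        min_sep = 2 * config.focal_width_mean_bp + 4 * spacing
        for polarity, hosts in (("gain", gain_hosts), ("loss", loss_hosts)):
            for chrom in hosts:
                span = _chrom_span(by_chrom[chrom], spacing)
                lo, hi = int(0.25 * span), int(0.9 * span)
                center = None
                for _ in range(200):
                    cand = int(rng.integers(lo, hi))
                    if all(abs(cand - t) >= min_sep for t in taken.get(chrom, [])):
                        center = cand
                        break
                if center is None:
                    continue  # chromosome too crowded; skip this focal
                taken.setdefault(chrom, []).append(center)
                driver = min(by_chrom[chrom], key=lambda g: abs(g.midpoint - center))
                truth.focal_drivers.append(
                    PlantedFocal(species, polarity, chrom, driver.gene_id, center)
                )


def _plant_mirnas(
    truth: TruthSet,
    human_genes: list[GeneRecord],
    fish_genes: list[GeneRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Lay out miRNA genes forming cross-species identifier families.

    The first ``n_concordant_gain_families`` families get one member on a
    recurrently gained chromosome in *each* species (and no member on any
    lost chromosome), the next ``n_concordant_loss_families`` the mirror
    image; the remaining families are neutral, altered in one species only,
    or deliberately vetoed (concordant members plus an opposite-polarity
    member).  miRNAs are placed in the first fifth of a chromosome, clear
    of the focal windows planted further along.
    """
    by_chrom = {
        Species.HUMAN: genes_by_chromosome(assign_ordinals(human_genes)),
        Species.FISH: genes_by_chromosome(assign_ordinals(fish_genes)),
    }
    chrom_sets = {}
    for species in (Species.HUMAN, Species.FISH):
        gains = truth.gain_chromosomes[species.value]
        losses = truth.loss_chromosomes[species.value]
        neutral = [
            c for c in by_chrom[species] if c not in gains and c not in losses
        ]
        chrom_sets[species] = {"gain": gains, "loss": losses, "neutral": neutral}

    out = {Species.HUMAN: [], Species.FISH: []}
    counters = {Species.HUMAN: 0, Species.FISH: 0}

    def place(species: Species, key: str, where: str, letter: str) -> None:
        chroms = chrom_sets[species][where]
        chrom = chroms[int(rng.integers(len(chroms)))]
        span = _chrom_span(by_chrom[species][chrom], config.spacing(species))
        start = int(rng.integers(int(0.02 * span), int(0.2 * span)))
        prefix = "hsa" if species == Species.HUMAN else "dre"
        counters[species] += 1
        out[species].append(
            GeneRecord(
                gene_id=f"{prefix}-mir-{key}{letter}",
                species=species,
                chromosome=chrom,
                start_bp=start,
                end_bp=start + 99,
                strand="+" if rng.random() < 0.5 else "-",
                biotype=Biotype.MIRNA,
            )
        )

    n_gain = config.n_concordant_gain_families
    n_loss = config.n_concordant_loss_families
    for k in range(1, config.n_mirna_families + 1):
        key = str(k)
        if k <= n_gain:
            truth.mirna_gain_families.append(key)
            place(Species.HUMAN, key, "gain", "")
            place(Species.FISH, key, "gain", "a")
            if rng.random() < 0.5:
                place(Species.FISH, key, "neutral", "b")
        elif k <= n_gain + n_loss:
            truth.mirna_loss_families.append(key)
            place(Species.HUMAN, key, "loss", "")
            place(Species.FISH, key, "loss", "a")
        else:
            pattern = (k - n_gain - n_loss) % 5
            if pattern == 0:  # neutral in both species
                place(Species.HUMAN, key, "neutral", "")
                place(Species.FISH, key, "neutral", "a")
            elif pattern == 1:  # altered in human only
                place(Species.HUMAN, key, "gain", "")
                place(Species.FISH, key, "neutral", "a")
            elif pattern == 2:  # altered in fish only
                place(Species.HUMAN, key, "neutral", "")
                place(Species.FISH, key, "loss", "a")
            elif pattern == 3:  # concordant gain vetoed by a lost member
                place(Species.HUMAN, key, "gain", "")
                place(Species.FISH, key, "gain", "a")
                place(Species.FISH, key, "loss", "b")
            else:  # discordant polarities
                place(Species.HUMAN, key, "gain", "")
                place(Species.FISH, key, "loss", "a")
    return out[Species.HUMAN], out[Species.FISH]


def _simulate_similarity(
    truth: TruthSet,
    human_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    p = config.similarity
    rows: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    # background hits only target humans with similarity evidence
    human_ids = sorted(set(truth.ortholog_pairs.values()))
    for fish_id in sorted(truth.ortholog_pairs):
        human_id = truth.ortholog_pairs[fish_id]
        mean = p.ortholog_score_mean
        if fish_id.endswith("B"):
            mean *= p.paralog_penalty
        score = mean + (rng.normal(0, p.ortholog_score_sd) if p.ortholog_score_sd else 0.0)
        rows.append((human_id, fish_id, max(score, 0.0)))
        seen.add((human_id, fish_id))
        for _ in range(rng.poisson(p.background_rate)):
            hg = human_ids[int(rng.integers(len(human_ids)))]
            if (hg, fish_id) in seen:
                continue
            bg = rng.normal(p.background_score_mean, p.background_score_sd)
            rows.append((hg, fish_id, float(np.clip(bg, 0.0, None))))
            seen.add((hg, fish_id))
    return pd.DataFrame(rows, columns=["human_gene_id", "fish_gene_id", "score"])


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    genes: Sequence[GeneRecord],
    truth: TruthSet,
    config: SimulationConfig,
    species: Species,
) -> tuple[list[SampleProfile], TruthSet]:
    """Simulate segmented tumor profiles for one species' cohort.

    Each sample starts at the 0 log2-ratio baseline everywhere; planted
    whole-chromosome events, focal events around the planted drivers,
    Poisson-rate passenger segments and chromothripsis oscillations are
    stacked on a per-gene-slot grid, compressed to segments, and per-segment
    Gaussian noise is added last.  The truth set is updated in place with
    the chromothripsis events actually planted.
    """
    focal_ids = {f.gene_id for f in truth.focals(species)}
    known = {g.gene_id for g in genes}
    missing = focal_ids - known
    if missing:
        raise ValueError(f"planted drivers not in annotation: {sorted(missing)}")

    rng = np.random.default_rng(
        [config.rng_seed, 2 if species == Species.FISH else 3]
    )
    spacing = config.spacing(species)
    by_chrom = genes_by_chromosome([g for g in genes if g.biotype == Biotype.PROTEIN_CODING])
    chroms = sorted(by_chrom, key=_chrom_sort)
    n_slots = {c: _chrom_span(by_chrom[c], spacing) // spacing for c in chroms}

    if species == Species.FISH:
        sample_plan = (
            [(f"rp_d_{i:03d}", GenotypeGroup.RP_DIPLOID) for i in range(config.n_rp_diploid)]
            + [(f"tp53_d_{i:03d}", GenotypeGroup.TP53_DIPLOID) for i in range(config.n_tp53_diploid)]
            + [(f"tp53_t_{i:03d}", GenotypeGroup.TP53_TRIPLOID) for i in range(config.n_tp53_triploid)]
        )
        baseline, gain_amp, loss_amp = 3, FISH_GAIN_AMP, FISH_LOSS_AMP
        ct_rate = config.chromothripsis_rate_fish
    else:
        sample_plan = [
            (f"nf1_{i:03d}", GenotypeGroup.HUMAN_NF1) for i in range(config.n_human_samples)
        ]
        baseline, gain_amp, loss_amp = 2, HUMAN_GAIN_AMP, HUMAN_LOSS_AMP
        ct_rate = config.chromothripsis_rate_human

    gain_chroms = set(truth.gain_chromosomes[species.value])
    loss_chroms = set(truth.loss_chromosomes[species.value])
    focals_by_chrom: dict[str, list[PlantedFocal]] = {}
    for f in truth.focals(species):
        focals_by_chrom.setdefault(f.chromosome, []).append(f)

    profiles: list[SampleProfile] = []
    for sample_id, group in sample_plan:
        tracks = {c: np.zeros(n_slots[c]) for c in chroms}
        for c in chroms:
            if c in gain_chroms and rng.random() < config.large_event_prob:
                tracks[c] += gain_amp
            if c in loss_chroms and rng.random() < config.large_event_prob:
                tracks[c] += loss_amp
            for focal in focals_by_chrom.get(c, []):
                if rng.random() >= config.focal_event_prob:
                    continue
                width = rng.normal(config.focal_width_mean_bp, config.focal_width_sd_bp)
                width = float(np.clip(width, 4 * spacing, 2 * config.focal_width_mean_bp))
                half = int(width / 2 // spacing)
                mid = focal.center_bp // spacing
                lo, hi = max(0, mid - half), min(n_slots[c], mid + half + 1)
                amp = config.focal_gain_amp if focal.polarity == "gain" else config.focal_loss_amp
                tracks[c][lo:hi] += amp
        # passengers: random intervals anywhere, one-copy amplitude
        for _ in range(rng.poisson(config.passenger_rate)):
            c = chroms[int(rng.integers(len(chroms)))]
            frac = rng.uniform(config.passenger_min_frac, config.passenger_max_frac)
            width = max(1, int(frac * n_slots[c]))
            start = int(rng.integers(0, max(1, n_slots[c] - width + 1)))
            amp = gain_amp if rng.random() < 0.5 else loss_amp
            tracks[c][start : start + width] += amp
        # chromothripsis: oscillation between two states over a window
        for c in chroms:
            if rng.random() >= ct_rate:
                continue
            win_frac = rng.uniform(0.4, 1.0)
            win = max(10, int(win_frac * n_slots[c]))
            start = int(rng.integers(0, n_slots[c] - win + 1))
            low, high = [
                (0.0, gain_amp),
                (loss_amp, 0.0),
                (loss_amp, gain_amp),
            ][int(rng.integers(3))]
            n_switch = int(rng.integers(7, 13))
            breaks = np.sort(
                rng.choice(np.arange(1, win), size=n_switch, replace=False)
            )
            bounds = np.concatenate([[0], breaks, [win]])
            phase = int(rng.integers(2))
            for i in range(len(bounds) - 1):
                val = low if (i + phase) % 2 == 0 else high
                tracks[c][start + bounds[i] : start + bounds[i + 1]] = val
            truth.chromothripsis_events.append((sample_id, species.value, c))

        segments: list[Segment] = []
        for c in chroms:
            for lo, hi, val in _runs(tracks[c]):
                noisy = val + (rng.normal(0, config.noise_sd) if config.noise_sd else 0.0)
                segments.append(
                    Segment(
                        chromosome=c,
                        start_bp=lo * spacing + 1,
                        end_bp=hi * spacing,
                        n_markers=hi - lo,
                        value=round(float(noisy), 6),
                    )
                )
        profiles.append(
            SampleProfile(
                sample_id=sample_id,
                genotype_group=group,
                baseline_ploidy=baseline,
                segments=segments,
            )
        )
    return profiles, truth


def _runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Compress an array into maximal constant runs [(start, end_excl, value)]."""
    out = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            out.append((start, i, float(values[start])))
            start = i
    return out


def simulate_study(config: SimulationConfig | None = None):
    """Run the full generator: genomes, similarity, truth and both cohorts.

    Returns ``(human_genes, fish_genes, similarity, fish_profiles,
    human_profiles, truth)``.
    """
    config = config or SimulationConfig()
    human_genes, fish_genes, similarity, truth = simulate_genomes(config)
    fish_profiles, truth = simulate_cohort(fish_genes, truth, config, Species.FISH)
    human_profiles, truth = simulate_cohort(human_genes, truth, config, Species.HUMAN)
    return human_genes, fish_genes, similarity, fish_profiles, human_profiles, truth


# ---------------------------------------------------------------------------
# fixtures and truth helpers


def emit_fixtures(
    outdir: str | Path,
    config: SimulationConfig | None = None,
) -> Path:
    """Write a complete synthetic study to ``outdir`` as TSV/SEG/YAML files.

    Output is deterministic given the config seed: two runs with the same
    seed produce byte-identical files.
    """
    config = config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    human_genes, fish_genes, similarity, fish_profiles, human_profiles, truth = (
        simulate_study(config)
    )
    write_genes(human_genes, outdir / "genes_human.tsv")
    write_genes(fish_genes, outdir / "genes_fish.tsv")
    write_similarity(similarity, outdir / "similarity.tsv")
    write_seg(fish_profiles, outdir / "fish_cohort.seg")
    write_seg(human_profiles, outdir / "human_cohort.seg")

    with open(outdir / "truth_orthologs.tsv", "w") as fh:
        fh.write("fish_gene_id\thuman_gene_id\n")
        for fish_id in sorted(truth.ortholog_pairs):
            fh.write(f"{fish_id}\t{truth.ortholog_pairs[fish_id]}\n")
    with open(outdir / "truth_events.tsv", "w") as fh:
        fh.write("kind\tspecies\tchromosome\tpolarity\tgene_id\tsample_id\n")
        for species in ("fish", "human"):
            for c in truth.gain_chromosomes[species]:
                fh.write(f"large\t{species}\t{c}\tgain\t.\t.\n")
            for c in truth.loss_chromosomes[species]:
                fh.write(f"large\t{species}\t{c}\tloss\t.\t.\n")
        for f in truth.focal_drivers:
            fh.write(
                f"focal\t{f.species.value}\t{f.chromosome}\t{f.polarity}\t"
                f"{f.gene_id}\t.\n"
            )
        for sample_id, species, chrom in truth.chromothripsis_events:
            fh.write(f"chromothripsis\t{species}\t{chrom}\t.\t.\t{sample_id}\n")
        for key in truth.mirna_gain_families:
            fh.write(f"mirna_family\tboth\t.\tgain\tmir-{key}\t.\n")
        for key in truth.mirna_loss_families:
            fh.write(f"mirna_family\tboth\t.\tloss\tmir-{key}\t.\n")
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return outdir


def regions_from_truth(
    truth: TruthSet,
    genes: Sequence[GeneRecord],
    species: Species,
    config: SimulationConfig,
) -> list[RecurrentRegion]:
    """Construct the planted recurrent regions directly from the truth set.

    Useful as an oracle input to the cross-species and miRNA stages when one
    wants to isolate them from the recurrence caller.
    """
    by_chrom = genes_by_chromosome(list(genes))
    regions: list[RecurrentRegion] = []
    for polarity, chrom_map in (
        ("gain", truth.gain_chromosomes),
        ("loss", truth.loss_chromosomes),
    ):
        for chrom in chrom_map[species.value]:
            members = by_chrom[chrom]
            regions.append(
                RecurrentRegion(
                    species=species,
                    chromosome=chrom,
                    start_bp=min(g.start_bp for g in members),
                    end_bp=max(g.end_bp for g in members),
                    polarity=polarity,
                    scope="large",
                    peak_gene_ids=[],
                    peak_q=0.0,
                    member_gene_ids=[g.gene_id for g in members],
                )
            )
    half = config.focal_width_mean_bp // 2
    for f in truth.focal_drivers:
        if f.species != species:
            continue
        lo, hi = f.center_bp - half, f.center_bp + half
        members = [g for g in by_chrom[f.chromosome] if lo <= g.midpoint <= hi]
        regions.append(
            RecurrentRegion(
                species=species,
                chromosome=f.chromosome,
                start_bp=lo,
                end_bp=hi,
                polarity=f.polarity,
                scope="focal",
                peak_gene_ids=[f.gene_id],
                peak_q=0.0,
                member_gene_ids=[g.gene_id for g in members],
            )
        )
    return regions
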