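"""Recurrence analysis of copy-number alterations across a tumor cohort.

The recurrence statistic is a G-score in the GISTIC family: for each gene
and polarity, the sample-averaged amplitude by which the gene's segment
value exceeds the cutoff theta,

    gains:  G(g) = (1/S) * sum_s max(0, v_gs - theta)
    losses: G(g) = (1/S) * sum_s max(0, -v_gs - theta)

Significance comes from a permutation null that independently permutes each
sample's gene values (preserving every sample's alteration burden while
destroying locus identity), pooling null G-scores over genes; p-values are
Benjamini-Hochberg adjusted into Q-values per polarity.

A "focal" mode removes per-sample chromosome background (the median value
of the chromosome in that sample) and then finds peaks iteratively with a
peel-off step, so focal events riding on whole-chromosome alterations are
still detected.  Region calling turns gene-level Q-values into contiguous
recurrent regions, split into chromosome-scale ("large") and focal calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .model import (
    Biotype,
    GeneRecord,
    PipelineConfig,
    SampleProfile,
    Species,
    genes_by_chromosome,
    _chrom_key,
)

__all__ = [
    "GeneCNMatrix",
    "GScoreResult",
    "RecurrentRegion",
    "FocalPeak",
    "gene_level_matrix",
    "gscore",
    "freq_track",
    "perm_qvalues",
    "score_matrix",
    "focal_transform",
    "focal_mode",
    "call_regions",
    "find_subpeaks",
    "cohort_ttest",
]

POLARITIES = ("gain", "loss")


@dataclass
class GeneCNMatrix:
    """Genes x samples matrix of segment log2 ratios.

    Genes are ordered by (chromosome, ordinal); ``values[i, j]`` is the
    value of the segment containing gene i's midpoint in sample j, relative
    to the sample's baseline ploidy.
    """

    genes: list[GeneRecord]
    sample_ids: list[str]
    values: np.ndarray
    species: Species
    baseline_note: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError("matrix shape does not match gene/sample lists")

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([g.chromosome for g in self.genes])

    def subset_genes(self, mask: np.ndarray) -> "GeneCNMatrix":
        return GeneCNMatrix(
            genes=[g for g, m in zip(self.genes, mask) if m],
            sample_ids=self.sample_ids,
            values=self.values[mask],
            species=self.species,
            baseline_note=self.baseline_note,
        )


@dataclass
class GScoreResult:
    """Per-gene recurrence scores for one polarity."""

    polarity: str
    g: np.ndarray
    p: np.ndarray
    q: np.ndarray
    freq: np.ndarray

    def neglog10_q(self) -> np.ndarray:
        return -np.log10(np.clip(self.q, 1e-300, None))


@dataclass
class FocalPeak:
    """A focal-mode peak after background removal and peel-off."""

    chromosome: str
    start_bp: int
    end_bp: int
    polarity: str
    peak_gene_id: str
    peak_q: float
    member_gene_ids: list[str] = field(default_factory=list)


@dataclass
class RecurrentRegion:
    """A maximal run of consecutive significant genes of one polarity."""

    species: Species
    chromosome: str
    start_bp: int
    end_bp: int
    polarity: str
    scope: str  # "large" | "focal"
    peak_gene_ids: list[str]
    peak_q: float
    member_gene_ids: list[str]

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start_bp <= position <= self.end_bp
        )


def gene_level_matrix(
    profiles: Sequence[SampleProfile],
    genes: Sequence[GeneRecord],
    species: Species | None = None,
    gap_fill: bool = True,
) -> GeneCNMatrix:
    """Assign each gene the value of the segment containing its midpoint.

    A midpoint on the first base of a segment takes that segment's value.
    Midpoints not covered by any segment take 0 (the baseline) when
    ``gap_fill`` is on, otherwise raise.
    """
    genes = sorted(genes, key=lambda g: (_chrom_key(g.chromosome), g.ordinal))
    species = species or genes[0].species
    by_chrom = genes_by_chromosome(list(genes))
    mids = {
        c: np.array([g.midpoint for g in gs]) for c, gs in by_chrom.items()
    }
    row_of = {g.gene_id: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(profiles)))
    for j, profile in enumerate(profiles):
        segs_by_chrom: dict[str, list] = {}
        for s in profile.segments:
            segs_by_chrom.setdefault(s.chromosome, []).append(s)
        for chrom, chrom_genes in by_chrom.items():
            segs = sorted(segs_by_chrom.get(chrom, []), key=lambda s: s.start_bp)
            if not segs:
                if not gap_fill:
                    raise ValueError(
                        f"sample {profile.sample_id}: no segments on chr{chrom}"
                    )
                continue
            starts = np.array([s.start_bp for s in segs])
            ends = np.array([s.end_bp for s in segs])
            vals = np.array([s.value for s in segs])
            idx = np.searchsorted(starts, mids[chrom], side="right") - 1
            covered = (idx >= 0) & (mids[chrom] <= ends[np.clip(idx, 0, None)])
            if not covered.all() and not gap_fill:
                bad = [g.gene_id for g, c in zip(chrom_genes, covered) if not c]
                raise ValueError(
                    f"sample {profile.sample_id}: genes not covered by any "
                    f"segment on chr{chrom}: {bad[:5]}"
                )
            rows = [row_of[g.gene_id] for g in chrom_genes]
            col = np.where(covered, vals[np.clip(idx, 0, None)], 0.0)
            values[rows, j] = col
    return GeneCNMatrix(
        genes=list(genes),
        sample_ids=[p.sample_id for p in profiles],
        values=values,
        species=species,
        baseline_note=f"log2 ratio vs {profiles[0].baseline_ploidy}N baseline"
        if profiles
        else "",
    )


def _excess(values: np.ndarray, theta: float, polarity: str) -> np.ndarray:
    signed = values if polarity == "gain" else -values
    return np.clip(signed - theta, 0.0, None)


def gscore(values: np.ndarray, theta: float, polarity: str) -> np.ndarray:
    """Sample-normalized G-score per gene (rows: genes, cols: samples)."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return _excess(values, theta, polarity).mean(axis=1)


def freq_track(values: np.ndarray, theta: float, polarity: str) -> np.ndarray:
    """Fraction of samples altered beyond theta in the given polarity."""
    signed = values if polarity == "gain" else -values
    return (signed > theta).mean(axis=1)


def perm_qvalues(
    values: np.ndarray,
    theta: float,
    polarity: str,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values and BH Q-values for the per-gene G-scores.

    The null permutes each sample's gene values independently and pools the
    resulting null G-scores over genes and permutations, so

        p(g) = (1 + #null >= G(g)) / (1 + N_null).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    excess = _excess(values, theta, polarity)
    g_obs = excess.mean(axis=1)
    null_pool = np.empty(n_perm * excess.shape[0])
    # permute the per-sample excess columns; the G-score only depends on the
    # excess, so permuting excess is equivalent to permuting raw values
    ex_t = np.ascontiguousarray(excess.T)  # samples x genes
    for k in range(n_perm):
        permuted = rng.permuted(ex_t, axis=1)
        null_pool[k * excess.shape[0] : (k + 1) * excess.shape[0]] = permuted.mean(
            axis=0
        )
    null_sorted = np.sort(null_pool)
    n_ge = len(null_sorted) - np.searchsorted(null_sorted, g_obs, side="left")
    p = (1.0 + n_ge) / (1.0 + len(null_sorted))
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def score_matrix(
    matrix: GeneCNMatrix,
    theta: float,
    polarity: str,
    n_perm: int = 200,
    seed: int = 0,
) -> GScoreResult:
    """G-score, permutation p, BH Q and frequency for one polarity."""
    p, q = perm_qvalues(matrix.values, theta, polarity, n_perm=n_perm, seed=seed)
    return GScoreResult(
        polarity=polarity,
        g=gscore(matrix.values, theta, polarity),
        p=p,
        q=q,
        freq=freq_track(matrix.values, theta, polarity),
    )


def focal_transform(matrix: GeneCNMatrix) -> GeneCNMatrix:
    """Subtract each sample's per-chromosome median value.

    Whole-chromosome events become ~0 and only departures from the
    chromosome background (focal events) survive.
    """
    values = matrix.values.copy()
    chroms = matrix.chromosomes
    for chrom in np.unique(chroms):
        rows = chroms == chrom
        values[rows] -= np.median(values[rows], axis=0, keepdims=True)
    return GeneCNMatrix(
        genes=matrix.genes,
        sample_ids=matrix.sample_ids,
        values=values,
        species=matrix.species,
        baseline_note=matrix.baseline_note + " (chromosome background removed)",
    )


def focal_mode(
    matrix: GeneCNMatrix,
    theta: float,
    polarity: str,
    q_cutoff: float,
    n_perm: int = 100,
    seed: int = 0,
    max_iter: int = 40,
) -> list[FocalPeak]:
    """Find focal peaks by iterative peel-off on the background-corrected matrix.

    Each round scores the matrix, takes the most significant gene, records
    the contiguous run of significant genes around it as a peak, zeroes the
    contribution of the supporting samples over that run, and re-scores,
    until no gene passes ``q_cutoff``.
    """
    corrected = focal_transform(matrix)
    values = corrected.values.copy()
    genes = corrected.genes
    chroms = corrected.chromosomes
    ordinals = np.array([g.ordinal for g in genes])
    peaks: list[FocalPeak] = []
    for it in range(max_iter):
        p, q = perm_qvalues(values, theta, polarity, n_perm=n_perm, seed=seed + it)
        g = gscore(values, theta, polarity)
        sig = q < q_cutoff
        if not sig.any():
            break
        peak_idx = int(np.argmax(np.where(sig, g, -np.inf)))
        run = _significant_run(sig, chroms, ordinals, peak_idx)
        member_ids = [genes[i].gene_id for i in run]
        # the maximal-overlap core of a focal event is a plateau of
        # near-equal G; report its central gene, not an arbitrary end
        plateau = [peak_idx]
        k = peak_idx
        while k - 1 in run and g[k - 1] >= 0.95 * g[peak_idx]:
            k -= 1
            plateau.insert(0, k)
        k = peak_idx
        while k + 1 in run and g[k + 1] >= 0.95 * g[peak_idx]:
            k += 1
            plateau.append(k)
        report_idx = plateau[len(plateau) // 2]
        peaks.append(
            FocalPeak(
                chromosome=genes[peak_idx].chromosome,
                start_bp=min(genes[i].start_bp for i in run),
                end_bp=max(genes[i].end_bp for i in run),
                polarity=polarity,
                peak_gene_id=genes[report_idx].gene_id,
                peak_q=float(q[report_idx]),
                member_gene_ids=member_ids,
            )
        )
        # peel off: remove the supporting samples' contribution over the run
        signed = values if polarity == "gain" else -values
        supporting = signed[peak_idx] > theta
        values[np.ix_(run, supporting)] = 0.0
    return peaks


def _significant_run(
    sig: np.ndarray, chroms: np.ndarray, ordinals: np.ndarray, idx: int
) -> list[int]:
    """Indices of the maximal run of significant, ordinal-consecutive genes
    on idx's chromosome containing idx."""
    run = [idx]
    i = idx
    while (
        i - 1 >= 0
        and sig[i - 1]
        and chroms[i - 1] == chroms[idx]
        and ordinals[i - 1] == ordinals[i] - 1
    ):
        i -= 1
        run.insert(0, i)
    i = idx
    while (
        i + 1 < len(sig)
        and sig[i + 1]
        and chroms[i + 1] == chroms[idx]
        and ordinals[i + 1] == ordinals[i] + 1
    ):
        i += 1
        run.append(i)
    return run


def call_regions(
    matrix: GeneCNMatrix,
    std_results: dict[str, GScoreResult],
    focal_peaks: dict[str, list[FocalPeak]],
    config: PipelineConfig,
) -> list[RecurrentRegion]:
    """Turn gene-level Q-values into binary region calls.

    Maximal runs of consecutive genes with Q below the species' cutoff
    become regions; a region is "focal" if it spans less than
    ``focal_max_span_bp`` or overlaps a focal-mode peak of the same
    polarity, otherwise "large".  Gain and loss regions may overlap.
    """
    q_cutoff = config.q_cutoff(matrix.species)
    genes = matrix.genes
    chroms = matrix.chromosomes
    ordinals = np.array([g.ordinal for g in genes])
    regions: list[RecurrentRegion] = []
    for polarity in POLARITIES:
        result = std_results[polarity]
        sig = result.q < q_cutoff
        i = 0
        while i < len(genes):
            if not sig[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < len(genes)
                and sig[j + 1]
                and chroms[j + 1] == chroms[i]
                and ordinals[j + 1] == ordinals[j] + 1
            ):
                j += 1
            run = list(range(i, j + 1))
            start = min(genes[k].start_bp for k in run)
            end = max(genes[k].end_bp for k in run)
            peak_k = run[int(np.argmin(result.q[run]))]
            # a focal peak supports the region only if it covers most of it;
            # a small amplification riding inside a whole-chromosome event
            # must not downgrade the chromosome-scale call
            member_set = {genes[k].gene_id for k in run}
            focal_supported = any(
                pk.chromosome == chroms[i]
                and len(member_set & set(pk.member_gene_ids)) >= 0.5 * len(member_set)
                for pk in focal_peaks.get(polarity, [])
            )
            scope = (
                "focal"
                if (end - start + 1) < config.focal_max_span_bp or focal_supported
                else "large"
            )
            regions.append(
                RecurrentRegion(
                    species=matrix.species,
                    chromosome=str(chroms[i]),
                    start_bp=start,
                    end_bp=end,
                    polarity=polarity,
                    scope=scope,
                    peak_gene_ids=[genes[peak_k].gene_id],
                    peak_q=float(result.q[peak_k]),
                    member_gene_ids=[genes[k].gene_id for k in run],
                )
            )
            i = j + 1
    return regions


def find_subpeaks(
    result: GScoreResult,
    region: RecurrentRegion,
    matrix: GeneCNMatrix,
    min_prominence: float = 0.5,
) -> list[tuple[str, float, float]]:
    """Local maxima of -log10 Q inside a region, the candidate sub-peaks.

    Returns ``(gene_id, -log10 q, prominence)`` sorted by peak height then
    leftmost position.  Boundary maxima count (a monotone track has its
    single peak at the end); plateaus resolve to their leftmost gene.
    """
    id_to_idx = {g.gene_id: i for i, g in enumerate(matrix.genes)}
    rows = [id_to_idx[gid] for gid in region.member_gene_ids]
    track = result.neglog10_q()[rows]
    padded = np.concatenate([[-np.inf], track, [-np.inf]])
    idx, props = signal.find_peaks(
        padded, prominence=min_prominence, plateau_size=1
    )
    peak_positions = props.get("left_edges", idx) - 1
    out = [
        (region.member_gene_ids[int(pos)], float(track[int(pos)]), float(prom))
        for pos, prom in zip(peak_positions, props["prominences"])
    ]
    if not out and len(track):
        pos = int(np.argmax(track))
        out = [(region.member_gene_ids[pos], float(track[pos]), float("inf"))]
    out.sort(key=lambda t: (-t[1], region.member_gene_ids.index(t[0])))
    return out


def cohort_ttest(
    matrix: GeneCNMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Two-tailed homoscedastic t-test of per-chromosome medians, per chromosome.

    Each sample is summarized by the median gene value on the chromosome;
    the two groups are then compared with a pooled-variance two-sample
    t-test.  Used to ask whether cohort subgroups (e.g. different
    initiating genotypes or ploidies) differ in their preference for a
    chromosome's alteration.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    ia = [col[s] for s in group_a]
    ib = [col[s] for s in group_b]
    chroms = matrix.chromosomes
    rows = []
    for chrom in sorted(set(chroms), key=_chrom_key):
        sub = matrix.values[chroms == chrom]
        med = np.median(sub, axis=0)
        a, b = med[ia], med[ib]
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.allclose(
            a.mean(), b.mean()
        ):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append((chrom, float(t), float(p)))
    return pd.DataFrame(rows, columns=["chromosome", "t", "p"])


def recurrence_tables(
    matrix: GeneCNMatrix, results: dict[str, GScoreResult]
) -> pd.DataFrame:
    """Per-gene G/Q/frequency long table for export and plotting."""
    rows = []
    for polarity, res in results.items():
        for g, gi, pi, qi, fi in zip(
            matrix.genes, res.g, res.p, res.q, res.freq
        ):
            rows.append(
                (
                    g.gene_id,
                    g.chromosome,
                    g.start_bp,
                    g.end_bp,
                    polarity,
                    gi,
                    pi,
                    qi,
                    fi,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chromosome",
            "start",
            "end",
            "polarity",
            "g_score",
            "p",
            "q",
            "frequency",
        ],
    )
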