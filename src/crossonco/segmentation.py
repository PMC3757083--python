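"""Binned tumor/normal log-ratio tracks and circular binary segmentation.

``compute_log_ratios`` turns paired tumor/normal bin counts into
library-size-scaled log2 ratios, median-centered genome-wide so the modal
copy-number state sits at 0 -- this is what anchors a near-triploid tumor
to its 3N baseline.

``cbs_segment`` is a circular binary segmentation: it recursively looks
for the arc (i, j) of the current (circularized) segment that maximizes
the two-sample t-statistic between the arc and its complement, accepts the
split when a within-segment permutation test gives p < alpha, and after
convergence merges back adjacent segments whose means differ by less than
``undo_sd`` pooled within-segment standard deviations (the "undo" step).
Single-bin outliers can be shrunk toward their neighbors first
(``smooth_outliers``).  The pipeline equally accepts externally segmented
SEG input, bypassing this module entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GenotypeGroup, SampleProfile, Segment

__all__ = [
    "BinnedTrack",
    "compute_log_ratios",
    "smooth_outliers",
    "cbs_segment",
    "undo_merge",
    "segment_profile",
]


@dataclass
class BinnedTrack:
    """Equal-grid tumor/normal read counts and log ratios for one chromosome."""

    sample_id: str
    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    tumor: np.ndarray
    normal: np.ndarray
    log2: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.ends) == len(self.tumor) == len(self.normal) == n):
            raise ValueError("bin arrays must have equal length")
        if np.any(self.starts[1:] <= self.ends[:-1]):
            raise ValueError("bins must be sorted and non-overlapping")


def compute_log_ratios(
    tracks: Sequence[BinnedTrack], pseudocount: float = 1.0
) -> list[BinnedTrack]:
    """Fill the log2 column of paired tumor/normal tracks for one sample.

    r_i = log2((t_i + c) / (n_i + c)) after scaling tumor counts to the
    normal library size, then median-centered over all bins of the sample
    so the baseline state is 0.  The pseudocount keeps zero-count bins
    finite.
    """
    t_total = sum(t.tumor.sum() for t in tracks)
    n_total = sum(t.normal.sum() for t in tracks)
    if t_total <= 0 or n_total <= 0:
        raise ValueError("tumor and normal totals must be > 0")
    scale = n_total / t_total
    raw = [
        np.log2((t.tumor * scale + pseudocount) / (t.normal + pseudocount))
        for t in tracks
    ]
    center = float(np.median(np.concatenate(raw)))
    out = []
    for track, r in zip(tracks, raw):
        out.append(
            BinnedTrack(
                sample_id=track.sample_id,
                chromosome=track.chromosome,
                starts=track.starts,
                ends=track.ends,
                tumor=track.tumor,
                normal=track.normal,
                log2=r - center,
            )
        )
    return out


def smooth_outliers(values: np.ndarray, z: float = 3.0) -> np.ndarray:
    """Shrink isolated single-bin outliers toward their neighbors.

    A bin further than ``z`` track-level standard deviations (robustly
    estimated from first differences) from *both* neighbors is set to the
    nearest neighbor value plus ``z * sd`` in its own direction; every
    other bin is untouched.  Applying the operation twice changes nothing
    after the first pass.
    """
    if len(values) < 3:
        return values.copy()
    diffs = np.diff(values)
    sd = float(np.median(np.abs(diffs - np.median(diffs)))) * 1.4826 / math.sqrt(2)
    out = values.copy()
    for i in range(1, len(values) - 1):
        d_prev = values[i] - values[i - 1]
        d_next = values[i] - values[i + 1]
        if abs(d_prev) > z * sd and abs(d_next) > z * sd and d_prev * d_next > 0:
            nearest = (
                values[i - 1]
                if abs(d_prev) <= abs(d_next)
                else values[i + 1]
            )
            out[i] = nearest + z * sd * np.sign(d_prev)
    return out


def _max_arc_t(values: np.ndarray) -> tuple[float, int, int]:
    """Best circular split of a segment: max |t| over arcs (i, j), i < j.

    The t-statistic compares the arc mean with the complement mean using
    the segment-wide variance estimate.  Returns (t, i, j) with the arc
    being values[i:j].
    """
    n = len(values)
    if n < 2:
        return 0.0, 0, n
    total = values.sum()
    var = values.var()
    if var == 0:
        return 0.0, 0, n
    csum = np.concatenate([[0.0], np.cumsum(values)])
    best_t, best_i, best_j = 0.0, 0, n
    # vectorize over j for each i
    for i in range(n):
        j = np.arange(i + 1, n + 1)
        k = j - i
        if i == 0:
            k = k[:-1]
            j = j[:-1]  # full-length arc is no split
            if len(j) == 0:
                continue
        arc_mean = (csum[j] - csum[i]) / k
        comp = (total - (csum[j] - csum[i])) / (n - k)
        t = np.abs(arc_mean - comp) / np.sqrt(var * (1.0 / k + 1.0 / (n - k)))
        m = int(np.argmax(t))
        if t[m] > best_t:
            best_t, best_i, best_j = float(t[m]), i, int(j[m])
    return best_t, best_i, best_j


def _split_pvalue(
    values: np.ndarray,
    observed_t: float,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value of the best split, with early stopping.

    Stops as soon as enough exceedances have accumulated to guarantee
    p >= alpha (the split will be rejected regardless of the remaining
    permutations).
    """
    threshold = math.ceil(alpha * (n_perm + 1))
    exceed = 0
    for k in range(n_perm):
        perm = rng.permutation(values)
        t, _, _ = _max_arc_t(perm)
        if t >= observed_t:
            exceed += 1
            if exceed >= threshold:
                return (1 + exceed) / (2 + k)
    return (1 + exceed) / (1 + n_perm)


def cbs_segment(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    undo_sd: float = 1.0,
    smooth: bool = True,
    seed: int = 0,
) -> list[tuple[int, int, float]]:
    """Segment a log-ratio track; returns (start_bin, end_bin_excl, mean).

    Splits are accepted at permutation p < alpha; adjacent segments whose
    means differ by less than ``undo_sd`` pooled within-segment standard
    deviations are merged afterwards.  Segment means are exactly the means
    of their member bins.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if len(values) == 0:
        return []
    rng = np.random.default_rng(seed)
    work = smooth_outliers(values) if smooth and len(values) >= 3 else values.copy()

    boundaries = [0, len(work)]
    stack = [(0, len(work))]
    while stack:
        lo, hi = stack.pop()
        seg = work[lo:hi]
        if len(seg) < 4:
            continue
        t, i, j = _max_arc_t(seg)
        if t == 0.0:
            continue
        p = _split_pvalue(seg, t, n_perm, alpha, rng)
        if p >= alpha:
            continue
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            continue
        pieces = [lo] + cuts + [hi]
        boundaries.extend(cuts)
        for a, b in zip(pieces, pieces[1:]):
            stack.append((a, b))
    boundaries = undo_merge(values, sorted(set(boundaries)), undo_sd)
    return [
        (a, b, float(values[a:b].mean()))
        for a, b in zip(boundaries, boundaries[1:])
    ]


def undo_merge(
    values: np.ndarray, boundaries: list[int], undo_sd: float
) -> list[int]:
    """The CBS "undo" step: drop breakpoints between similar segments.

    Adjacent segments whose means differ by less than ``undo_sd`` pooled
    within-segment standard deviations are merged, most similar pair
    first, until every remaining neighbor pair clears the threshold.
    """

    def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
        dof = len(a) + len(b) - 2
        if dof <= 0:
            return 0.0
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        return math.sqrt(ss / dof)

    boundaries = list(boundaries)
    while len(boundaries) > 2:
        gaps = []
        for k in range(1, len(boundaries) - 1):
            a = values[boundaries[k - 1] : boundaries[k]]
            b = values[boundaries[k] : boundaries[k + 1]]
            sd = pooled_sd(a, b)
            diff = abs(a.mean() - b.mean())
            gaps.append((diff - undo_sd * sd, k))
        margin, k = min(gaps)
        if margin < 0:
            boundaries.pop(k)
        else:
            break
    return boundaries


def segment_profile(
    tracks: Sequence[BinnedTrack],
    sample_id: str,
    genotype_group: GenotypeGroup,
    baseline_ploidy: int,
    alpha: float = 0.01,
    n_perm: int = 1000,
    undo_sd: float = 1.0,
    smooth: bool = True,
    seed: int = 0,
) -> SampleProfile:
    """Segment all chromosomes of a sample into a :class:`SampleProfile`."""
    segments = []
    for track in tracks:
        if len(track.log2) == 0:
            raise ValueError("tracks must have log2 ratios; run compute_log_ratios")
        for lo, hi, mean in cbs_segment(
            track.log2, alpha=alpha, n_perm=n_perm, undo_sd=undo_sd,
            smooth=smooth, seed=seed,
        ):
            segments.append(
                Segment(
                    chromosome=track.chromosome,
                    start_bp=int(track.starts[lo]),
                    end_bp=int(track.ends[hi - 1]),
                    n_markers=hi - lo,
                    value=mean,
                )
            )
    return SampleProfile(
        sample_id=sample_id,
        genotype_group=genotype_group,
        baseline_ploidy=baseline_ploidy,
        segments=segments,
    )
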