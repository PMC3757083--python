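"""Chromothripsis-pattern flagging from segmented copy-number profiles.

The operational signature is a copy-number profile that oscillates between
a small number of discrete states (two or three) along all or part of a
chromosome.  Segments are discretized into loss / neutral / gain states
around a log2-ratio band ``delta``; a sample-chromosome is flagged when a
window covering at least ``min_span`` of the chromosome contains at least
``min_switches`` adjacent state changes while using at most ``max_states``
distinct states.  This is a CNA-pattern heuristic only -- no structural
variant (junction) evidence enters.
"""

from __future__ import annotations

from dataclasses import dataclass
import statistics
from typing import Sequence

import pandas as pd

from .model import ChromothripsisParams, SampleProfile, Segment, _chrom_key

__all__ = ["ChromothripsisCall", "discretize_states", "detect", "detect_cohort"]


@dataclass
class ChromothripsisCall:
    sample_id: str
    chromosome: str
    n_segments: int
    n_states: int
    n_switches: int
    span_fraction: float
    flagged: bool


def discretize_states(
    segments: Sequence[Segment], delta: float = 0.2
) -> list[tuple[str, int, int]]:
    """Collapse a chromosome's segments into merged state runs.

    Returns ``(state, start_bp, end_bp)`` runs with state in
    {"loss", "neutral", "gain"}: loss below -delta, gain above +delta.
    Consecutive equal states are merged, so splitting a segment in two
    never changes the run sequence or the switch count.
    """
    runs: list[tuple[str, int, int]] = []
    for seg in sorted(segments, key=lambda s: s.start_bp):
        state = "gain" if seg.value > delta else "loss" if seg.value < -delta else "neutral"
        if runs and runs[-1][0] == state:
            runs[-1] = (state, runs[-1][1], seg.end_bp)
        else:
            runs.append((state, seg.start_bp, seg.end_bp))
    return runs


def _window_span(chain: list[tuple[str, int, int]]) -> int:
    """Span of an oscillating window, with boundary runs capped.

    The first and last run of a chain absorb whatever background flanks the
    oscillation (a long quiet stretch merges into the chain's end state),
    so they contribute at most the chain's median run length; interior runs
    count in full.
    """
    lengths = [end - start + 1 for _, start, end in chain]
    if len(lengths) <= 2:
        return sum(lengths)
    cap = statistics.median(lengths)
    return (
        sum(lengths[1:-1])
        + min(lengths[0], cap)
        + min(lengths[-1], cap)
    )


def detect(
    profile: SampleProfile,
    params: ChromothripsisParams | None = None,
) -> list[ChromothripsisCall]:
    """Flag oscillating chromosomes in one sample; one call per chromosome.

    The oscillating window is the run sub-sequence maximizing the number of
    switches subject to using at most ``max_states`` distinct states;
    flagged iff that window has >= ``min_switches`` switches and spans
    >= ``min_span`` of the chromosome.  Deterministic given the profile.
    """
    params = params or ChromothripsisParams()
    by_chrom: dict[str, list[Segment]] = {}
    for seg in profile.segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    calls: list[ChromothripsisCall] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        segs = by_chrom[chrom]
        runs = discretize_states(segs, params.delta)
        chrom_span = max(s.end_bp for s in segs) - min(s.start_bp for s in segs) + 1
        # the oscillating window is a maximal chain of runs that toggle
        # between exactly two states (adjacent runs always differ after
        # merging, so the constraint is that run i matches run i-2); sparse
        # isolated events sprinkled along a chromosome break such chains,
        # genuine shattering patterns do not
        best = (0, 0, 0.0)  # switches, states, span fraction
        i = 0
        while i < len(runs):
            pair = {runs[i][0]}
            j = i
            while j + 1 < len(runs) and (
                len(pair | {runs[j + 1][0]}) <= 2
            ):
                pair.add(runs[j + 1][0])
                j += 1
            switches = j - i
            span = _window_span(runs[i : j + 1]) / chrom_span
            if switches > best[0] or (switches == best[0] and span > best[2]):
                best = (switches, len(pair), span)
            i = max(i + 1, j)
        n_switches, n_states, span_frac = best
        flagged = (
            n_switches >= params.min_switches
            and 2 <= n_states <= params.max_states
            and span_frac >= params.min_span
        )
        calls.append(
            ChromothripsisCall(
                sample_id=profile.sample_id,
                chromosome=chrom,
                n_segments=len(segs),
                n_states=n_states,
                n_switches=n_switches,
                span_fraction=round(span_frac, 4),
                flagged=flagged,
            )
        )
    return calls


def detect_cohort(
    profiles: Sequence[SampleProfile],
    params: ChromothripsisParams | None = None,
) -> pd.DataFrame:
    """Run detection over a cohort; one row per sample-chromosome."""
    rows = []
    for p in profiles:
        for c in detect(p, params):
            rows.append(
                {
                    "sample": c.sample_id,
                    "chromosome": c.chromosome,
                    "n_segments": c.n_segments,
                    "n_states": c.n_states,
                    "n_switches": c.n_switches,
                    "span_fraction": c.span_fraction,
                    "flagged": c.flagged,
                }
            )
    return pd.DataFrame(rows)
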