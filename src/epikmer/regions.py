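"""Fold-change region calling and promoter/enhancer/other classification.

A region is "activated" when the treated-over-control ratio of its
normalized signal (mean bin value scaled to signal-per-million of library
total, pseudocount-stabilized) strictly exceeds the fold threshold —
"more than 3-fold" is read literally as ``fold > 3.0``. Called regions are
then classified by their histone-mark context: H3K4me3-positive regions
near a TSS are promoters, H3K4me2-positive/H3K4me3-negative regions are
enhancers, everything else is other.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

import numpy as np

from .core import AnalysisParams, ChromatinState, CoverageTrack, GenomicInterval


@dataclass(frozen=True)
class DifferentialRegion:
    """A candidate interval annotated with per-condition signal and fold."""

    interval: GenomicInterval
    center: int
    mark: str
    signal_treated: float
    signal_control: float
    fold_change: float
    state: ChromatinState | None = None

    def __post_init__(self) -> None:
        if not self.interval.start <= self.center < self.interval.end:
            raise ValueError("center must lie within the interval")


def quantify_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Overlap-weighted mean bin value over the interval, per million.

    Partial bins are weighted by their overlap length; the mean is scaled
    by 1e6 / library_total.
    """
    if interval.contig not in track.data:
        raise ValueError(f"contig {interval.contig!r} not in track")
    values = track.data[interval.contig]
    bs = track.bin_size
    if interval.start < 0 or interval.end > len(values) * bs:
        raise ValueError(f"interval {interval} outside track bounds")
    first, last = interval.start // bs, (interval.end - 1) // bs
    total = 0.0
    for b in range(first, last + 1):
        lo = max(interval.start, b * bs)
        hi = min(interval.end, (b + 1) * bs)
        total += values[b] * (hi - lo)
    mean = total / len(interval)
    if track.library_total == 0:
        return 0.0
    return mean * 1e6 / track.library_total


def detect_peaks(
    track: CoverageTrack, min_signal: float, merge_distance: int
) -> list[GenomicInterval]:
    """Maximal runs of bins above ``min_signal`` (raw units), merged.

    Runs separated by less than ``merge_distance`` bases are merged; the
    interval name carries the center, defined as the midpoint of the
    leftmost maximal bin in the run.
    """
    if min_signal <= 0:
        raise ValueError("min_signal must be positive")
    peaks = []
    bs = track.bin_size
    for contig, values in track.data.items():
        above = values > min_signal
        runs: list[tuple[int, int]] = []
        i = 0
        n = len(values)
        while i < n:
            if above[i]:
                j = i
                while j + 1 < n and above[j + 1]:
                    j += 1
                if runs and (i - runs[-1][1]) * bs < merge_distance:
                    runs[-1] = (runs[-1][0], j + 1)
                else:
                    runs.append((i, j + 1))
                i = j + 1
            else:
                i += 1
        for b0, b1 in runs:
            apex_bin = b0 + int(np.argmax(values[b0:b1]))
            center = apex_bin * bs + bs // 2
            peaks.append(
                GenomicInterval(contig, b0 * bs, b1 * bs, name=f"center={center}")
            )
    return peaks


def peak_center(interval: GenomicInterval) -> int:
    """Center of a candidate: a detect_peaks apex if recorded, else midpoint."""
    if interval.name and interval.name.startswith("center="):
        return int(interval.name.removeprefix("center="))
    return interval.center


def call_increased_regions(
    treated: CoverageTrack,
    control: CoverageTrack,
    candidates: list[GenomicInterval],
    mark: str,
    params: AnalysisParams | None = None,
    fold_threshold: float | None = None,
) -> list[DifferentialRegion]:
    """Candidates whose pseudocounted fold change strictly exceeds threshold.

    fold = (signal_treated + pseudocount) / (signal_control + pseudocount),
    both signals in per-million units. The output is sorted by descending
    fold change; passing ``fold_threshold`` explicitly (e.g. the secondary
    1.5 threshold) overrides ``params.fold_threshold``.
    """
    params = params or AnalysisParams()
    if treated.bin_size != control.bin_size:
        raise ValueError("treated and control tracks must share bin_size")
    threshold = params.fold_threshold if fold_threshold is None else fold_threshold
    pc = params.pseudocount
    regions = []
    for candidate in candidates:
        sig_t = quantify_signal(treated, candidate)
        sig_c = quantify_signal(control, candidate)
        fold = (sig_t + pc) / (sig_c + pc)
        if fold > threshold:
            regions.append(
                DifferentialRegion(
                    interval=candidate,
                    center=peak_center(candidate),
                    mark=mark,
                    signal_treated=sig_t,
                    signal_control=sig_c,
                    fold_change=fold,
                )
            )
    regions.sort(key=lambda r: -r.fold_change)
    return regions


def mark_positive_threshold(track: CoverageTrack) -> float:
    """Default mark-positivity threshold: 2x the genome-wide median, in RPM."""
    values = np.concatenate([v for v in track.data.values()])
    return 2.0 * float(np.median(values)) * 1e6 / track.library_total


def classify_region(
    region: DifferentialRegion,
    tss_positions: dict[str, list[int]],
    h3k4me2: CoverageTrack,
    h3k4me3: CoverageTrack,
    params: AnalysisParams | None = None,
    mark_threshold: float | None = None,
) -> DifferentialRegion:
    """Assign PROMOTER / ENHANCER / OTHER from mark context and TSS distance.

    PROMOTER: H3K4me3 signal above ``mark_threshold`` and the center within
    ``params.promoter_tss_distance`` of the nearest TSS. ENHANCER: H3K4me2
    above threshold with H3K4me3 at or below it. Everything else: OTHER.
    """
    params = params or AnalysisParams()
    if not any(tss_positions.values()):
        raise ValueError("TSS list must be non-empty")
    if mark_threshold is None:
        mark_threshold = mark_positive_threshold(h3k4me3)
    if mark_threshold <= 0:
        raise ValueError("mark_threshold must be positive")
    sig_me3 = quantify_signal(h3k4me3, region.interval)
    sig_me2 = quantify_signal(h3k4me2, region.interval)
    tss = tss_positions.get(region.interval.contig, [])
    tss_dist = _nearest_distance(tss, region.center) if tss else None
    if (
        sig_me3 > mark_threshold
        and tss_dist is not None
        and tss_dist <= params.promoter_tss_distance
    ):
        state = ChromatinState.PROMOTER
    elif sig_me2 > mark_threshold and sig_me3 <= mark_threshold:
        state = ChromatinState.ENHANCER
    else:
        state = ChromatinState.OTHER
    return replace(region, state=state)


def _nearest_distance(sorted_positions: list[int], point: int) -> int:
    i = bisect.bisect_left(sorted_positions, point)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(sorted_positions):
            d = abs(sorted_positions[j] - point)
            best = d if best is None else min(best, d)
    assert best is not None
    return best
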