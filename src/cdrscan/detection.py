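"""The core dip caller.

Candidate bins are alpha-satellite bins whose mean methylation falls far
enough below the regional median; consecutive candidates form valleys,
valleys are filtered by topographic prominence, boundaries are extended
outward to the mean-minus-k-SD level, and nearby calls are merged.

Thresholds are median-relative by default: with ``depth_fraction`` d the
candidate cutoff is ``median * (1 - d)`` and with ``prominence_fraction``
p the prominence cutoff is ``p * median``.  An absolute-threshold mode
(cutoffs used as raw frequencies) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .binning import BinnedProfile
from .errors import NoAlphaSignalError, UsageError
from .io import CdrCall, GenomicInterval

Signal = list[tuple[int, float]]  # (bin index in profile, mean_freq)


@dataclass(frozen=True)
class DetectionParams:
    """Tuning knobs of the caller; defaults follow the published settings."""

    bin_size: int = 5000
    depth_fraction: float = 0.34
    prominence_fraction: float = 0.30
    edge_sd_multiplier: float = 1.0
    merge_gap_bins: int = 1
    absolute_thresholds: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise UsageError("bin_size must be positive")
        if not (0 < self.depth_fraction < 1):
            raise UsageError("depth_fraction must be in (0, 1)")
        if not (0 <= self.prominence_fraction < 1):
            raise UsageError("prominence_fraction must be in [0, 1)")
        if self.edge_sd_multiplier < 0:
            raise UsageError("edge_sd_multiplier must be >= 0")
        if self.merge_gap_bins < 0:
            raise UsageError("merge_gap_bins must be >= 0")

    def candidate_threshold(self, median: float) -> float:
        if self.absolute_thresholds:
            return self.depth_fraction
        return median * (1.0 - self.depth_fraction)

    def prominence_cutoff(self, median: float) -> float:
        if self.absolute_thresholds:
            return self.prominence_fraction
        return self.prominence_fraction * median


@dataclass(frozen=True)
class SignalStats:
    """Median / mean / population SD over the valid alpha-bin signal."""

    median: float
    mean: float
    sd: float
    n_alpha_bins: int


@dataclass
class CandidateValley:
    """A maximal run of candidate bins, indexed into the full profile."""

    bin_index_range: tuple[int, int]  # inclusive
    min_index: int
    min_value: float
    prominence: float = math.nan


def alpha_signal(profile: BinnedProfile) -> Signal:
    """Valid alpha bins of *profile*, in genomic order, as (index, value)."""
    signal = [(i, b.mean_freq) for i, b in enumerate(profile.bins)
              if b.is_alpha and b.is_valid]
    if not signal:
        raise NoAlphaSignalError(
            f"no valid alpha-satellite bins in region {profile.region}")
    return signal


def signal_stats(signal: Signal) -> SignalStats:
    """Median, mean, and population (1/n) SD of the signal values."""
    if not signal:
        raise UsageError("signal_stats requires a non-empty signal")
    values = np.array([v for _, v in signal], dtype=np.float64)
    return SignalStats(
        median=float(np.median(values)),
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        n_alpha_bins=len(values))


def _side_bound(values: Sequence[float], idx: int, step: int) -> float:
    """Max value seen walking from *idx* until one strictly below values[idx].

    Returns +inf if the side is empty, so an edge valley is bounded by the
    other side alone.
    """
    floor = values[idx]
    best = -math.inf
    i = idx + step
    n = len(values)
    while 0 <= i < n:
        best = max(best, values[i])
        if values[i] < floor:
            break
        i += step
    return best if best > -math.inf else math.inf


def _prominence_unchecked(values: Sequence[float], idx: int) -> float:
    left = _side_bound(values, idx, -1)
    right = _side_bound(values, idx, +1)
    bound = min(left, right)
    if math.isinf(bound):  # single-element signal
        return 0.0
    return bound - values[idx]


def valley_prominence(values: Sequence[float], idx: int) -> float:
    """Topographic prominence of the valley at *idx* (inverted signal).

    Walk left from *idx* until a value strictly lower than ``values[idx]``
    is found or the sequence ends, recording the maximum seen; likewise
    right; prominence is the smaller of the two maxima minus
    ``values[idx]``.  A side with no elements imposes no bound.
    """
    if not (0 <= idx < len(values)):
        raise UsageError(f"index {idx} out of range")
    if (idx > 0 and values[idx - 1] < values[idx]) or \
            (idx < len(values) - 1 and values[idx + 1] < values[idx]):
        raise UsageError(f"values[{idx}] is not a local minimum")
    return _prominence_unchecked(values, idx)


def find_candidate_valleys(signal: Signal, stats: SignalStats,
                           params: DetectionParams) -> list[CandidateValley]:
    """Group below-threshold bins into valleys and score their prominence.

    Candidate bins have value strictly below the candidate threshold.
    Runs are defined by genomic adjacency of bin indices in the full
    profile, so an excluded (invalid or non-alpha) bin splits a run.  The
    deepest bin seeds each valley (leftmost on ties); its prominence is
    evaluated on the alpha-bin subsequence.
    """
    threshold = params.candidate_threshold(stats.median)
    values = [v for _, v in signal]

    valleys: list[CandidateValley] = []
    run: list[int] = []  # positions within `signal`
    for pos, (bin_idx, value) in enumerate(signal):
        if value < threshold:
            if run and signal[run[-1]][0] == bin_idx - 1:
                run.append(pos)
            else:
                if run:
                    valleys.append(_close_run(signal, values, run))
                run = [pos]
        else:
            if run:
                valleys.append(_close_run(signal, values, run))
                run = []
    if run:
        valleys.append(_close_run(signal, values, run))
    return valleys


def _close_run(signal: Signal, values: list[float],
               run: list[int]) -> CandidateValley:
    min_pos = min(run, key=lambda p: (signal[p][1], p))
    return CandidateValley(
        bin_index_range=(signal[run[0]][0], signal[run[-1]][0]),
        min_index=signal[min_pos][0],
        min_value=signal[min_pos][1],
        prominence=_prominence_unchecked(values, min_pos))


def filter_by_prominence(candidates: Sequence[CandidateValley],
                         signal: Signal, stats: SignalStats,
                         params: DetectionParams) -> list[CandidateValley]:
    """Keep valleys whose prominence meets the cutoff; order preserved."""
    cutoff = params.prominence_cutoff(stats.median)
    return [c for c in candidates if c.prominence >= cutoff]


def extend_boundaries(candidate: CandidateValley, profile: BinnedProfile,
                      stats: SignalStats,
                      params: DetectionParams) -> CandidateValley:
    """Grow the valley outward while neighbours stay below mean - k*SD.

    Extension proceeds one bin at a time on each side independently and
    never crosses an invalid or non-alpha bin.
    """
    threshold = stats.mean - params.edge_sd_multiplier * stats.sd
    bins = profile.bins
    lo, hi = candidate.bin_index_range
    while lo > 0:
        b = bins[lo - 1]
        if b.is_valid and b.is_alpha and b.mean_freq < threshold:
            lo -= 1
        else:
            break
    while hi < len(bins) - 1:
        b = bins[hi + 1]
        if b.is_valid and b.is_alpha and b.mean_freq < threshold:
            hi += 1
        else:
            break
    return replace(candidate, bin_index_range=(lo, hi))


def merge_calls(calls: Sequence[CandidateValley],
                params: DetectionParams) -> list[CandidateValley]:
    """Merge calls whose bin ranges overlap or nearly touch.

    Two calls merge when separated by at most ``merge_gap_bins`` bins.
    The merged valley keeps the deepest member's seed (leftmost on ties)
    and the maximum prominence over members.
    """
    if not calls:
        return []
    ordered = sorted(calls, key=lambda c: c.bin_index_range)
    merged = [replace(ordered[0])]
    for call in ordered[1:]:
        prev = merged[-1]
        gap = call.bin_index_range[0] - prev.bin_index_range[1] - 1
        if gap <= params.merge_gap_bins:
            lo = prev.bin_index_range[0]
            hi = max(prev.bin_index_range[1], call.bin_index_range[1])
            if (call.min_value, call.min_index) < \
                    (prev.min_value, prev.min_index):
                min_index, min_value = call.min_index, call.min_value
            else:
                min_index, min_value = prev.min_index, prev.min_value
            merged[-1] = CandidateValley(
                bin_index_range=(lo, hi), min_index=min_index,
                min_value=min_value,
                prominence=max(prev.prominence, call.prominence))
        else:
            merged.append(replace(call))
    return merged


def call_cdrs(profile: BinnedProfile,
              params: DetectionParams | None = None) -> list[CdrCall]:
    """Run the full caller on an annotated profile.

    Deterministic for fixed input and parameters.  Raises
    :class:`NoAlphaSignalError` when the region has no valid alpha bins.
    """
    if params is None:
        params = DetectionParams()
    signal = alpha_signal(profile)
    stats = signal_stats(signal)
    candidates = find_candidate_valleys(signal, stats, params)
    survivors = filter_by_prominence(candidates, signal, stats, params)
    extended = [extend_boundaries(c, profile, stats, params)
                for c in survivors]
    final = merge_calls(extended, params)

    region = profile.region
    calls: list[CdrCall] = []
    for valley in final:
        lo, hi = valley.bin_index_range
        start = profile.bins[lo].interval.start
        end = profile.bins[hi].interval.end
        calls.append(CdrCall(
            interval=GenomicInterval(region.chrom, start, end,
                                     name=region.name),
            min_freq=valley.min_value,
            prominence=valley.prominence,
            seed_bin_index=valley.min_index,
            region_median=stats.median,
            region_mean=stats.mean,
            region_sd=stats.sd))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


__all__ = [
    "DetectionParams", "SignalStats", "CandidateValley", "alpha_signal",
    "signal_stats", "valley_prominence", "find_candidate_valleys",
    "filter_by_prominence", "extend_boundaries", "merge_calls", "call_cdrs",
]
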