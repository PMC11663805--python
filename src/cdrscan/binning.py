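"""Aggregate per-CpG records into fixed-width bins over a target region.

The bin grid is anchored at the region start; the final bin may be
shorter than ``bin_size`` and is retained.  A CpG belongs to the bin
containing its start coordinate.  Bin means are unweighted means of the
per-CpG frequencies unless coverage weighting is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyRegionError, UsageError
from .io import GenomicInterval, MethylRecord, RepeatAnnotation

log = logging.getLogger(__name__)

ALPHA_REPEAT_NAME = "ALR/Alpha"


@dataclass
class MethylBin:
    """One fixed-width bin of aggregated CpG methylation."""

    interval: GenomicInterval
    mean_freq: float | None
    n_cpg: int
    is_alpha: bool = False
    mean_valid_cov: float = 0.0
    mean_mod_cov: float = 0.0

    @property
    def is_valid(self) -> bool:
        return self.n_cpg > 0


@dataclass
class BinnedProfile:
    """Ordered bins tiling one target region end-to-end."""

    region: GenomicInterval
    bin_size: int
    bins: list[MethylBin]

    def __len__(self) -> int:
        return len(self.bins)


def make_bins(region: GenomicInterval, bin_size: int) -> list[GenomicInterval]:
    """Tile *region* with ``ceil(length / bin_size)`` sequential intervals."""
    if bin_size <= 0:
        raise UsageError(f"bin_size must be positive, got {bin_size}")
    bins = []
    start = region.start
    while start < region.end:
        end = min(start + bin_size, region.end)
        bins.append(GenomicInterval(region.chrom, start, end))
        start = end
    return bins


def bin_methylation(records: Sequence[MethylRecord],
                    region: GenomicInterval,
                    bin_size: int = 5000,
                    coverage_weighted: bool = False) -> BinnedProfile:
    """Bin per-CpG records into a :class:`BinnedProfile` over *region*.

    Each bin's ``mean_freq`` is the unweighted arithmetic mean of ``freq``
    over CpGs whose start lies in the bin (coverage-weighted on request).
    Bins with no CpGs are invalid and excluded from downstream analysis.
    Records outside the region are ignored with a logged count.
    """
    intervals = make_bins(region, bin_size)
    n_bins = len(intervals)

    in_region = [r for r in records
                 if region.contains_point(r.chrom, r.start)]
    n_out = len(records) - len(in_region)
    if n_out:
        log.info("ignored %d records outside region %s", n_out, region)
    if not in_region:
        raise EmptyRegionError(region)
    # canonical order makes the floating-point bin sums independent of
    # input record order
    in_region.sort(key=lambda r: (r.start, r.freq, r.valid_cov, r.n_mod))

    starts = np.array([r.start for r in in_region], dtype=np.int64)
    freqs = np.array([r.freq for r in in_region], dtype=np.float64)
    covs = np.array([r.valid_cov for r in in_region], dtype=np.float64)
    mods = np.array([r.n_mod for r in in_region], dtype=np.float64)

    idx = (starts - region.start) // bin_size
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    freq_sum = np.bincount(idx, weights=freqs, minlength=n_bins)
    cov_sum = np.bincount(idx, weights=covs, minlength=n_bins)
    mod_sum = np.bincount(idx, weights=mods, minlength=n_bins)
    wfreq_sum = np.bincount(idx, weights=freqs * covs, minlength=n_bins)

    bins: list[MethylBin] = []
    for i, iv in enumerate(intervals):
        n = int(counts[i])
        if n == 0:
            bins.append(MethylBin(interval=iv, mean_freq=None, n_cpg=0))
            continue
        if coverage_weighted and cov_sum[i] > 0:
            mean_freq = float(wfreq_sum[i] / cov_sum[i])
        else:
            mean_freq = float(freq_sum[i] / n)
        bins.append(MethylBin(
            interval=iv, mean_freq=mean_freq, n_cpg=n,
            mean_valid_cov=float(cov_sum[i] / n),
            mean_mod_cov=float(mod_sum[i] / n)))
    return BinnedProfile(region=region, bin_size=bin_size, bins=bins)


def annotate_alpha_bins(profile: BinnedProfile,
                        annotations: Sequence[RepeatAnnotation],
                        alpha_name: str = ALPHA_REPEAT_NAME,
                        min_overlap_fraction: float = 0.0) -> BinnedProfile:
    """Mark bins overlapping an alpha-satellite annotation.

    A bin is alpha iff it overlaps >= 1 bp (or, when
    ``min_overlap_fraction`` > 0, that fraction of its own length) of an
    annotation whose ``repeat_name`` equals *alpha_name* exactly
    (case-sensitive).  The mask is recomputed from scratch on each call.
    """
    alpha = [a.interval for a in annotations
             if a.repeat_name == alpha_name
             and a.interval.chrom == profile.region.chrom]
    for b in profile.bins:
        overlap = 0
        for iv in alpha:
            lo = max(b.interval.start, iv.start)
            hi = min(b.interval.end, iv.end)
            if hi > lo:
                overlap += hi - lo
        if min_overlap_fraction > 0:
            b.is_alpha = overlap >= min_overlap_fraction * b.interval.length
        else:
            b.is_alpha = overlap >= 1
    return profile


__all__ = ["MethylBin", "BinnedProfile", "make_bins", "bin_methylation",
           "annotate_alpha_bins", "ALPHA_REPEAT_NAME"]
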