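"""Seeded generator of centromeric methylation fixtures.

Emulates the data regime of a hypermethylated alpha-satellite higher-order
repeat array carrying one or more hypomethylated dips: CpG sites with
geometric spacing, Poisson read coverage, binomial methylated counts, and
linear ramps centred on each planted dip edge.  Everything is reproducible
from the seed and written in the exact dialects the readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError, UsageError
from .io import (GenomicInterval, MethylRecord, RepeatAnnotation,
                 write_interval_bed)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic centromeric region."""

    region_length: int = 3_000_000
    region_start: int = 0
    chrom: str = "chrSim"
    alpha_array: GenomicInterval | None = None  # default: central 2 Mbp
    cpg_mean_spacing: int = 60
    baseline_meth: float = 0.85
    dip_meth: float = 0.10
    n_dips: int = 1
    dip_length_range: tuple[int, int] = (60_000, 150_000)
    edge_ramp: int = 10_000
    mean_coverage: int = 30
    seed: int = 0
    dip_intervals: tuple[tuple[int, int], ...] | None = None  # explicit dips

    def __post_init__(self) -> None:
        if not (0.0 <= self.dip_meth <= self.baseline_meth <= 1.0):
            raise UsageError(
                "require 0 <= dip_meth <= baseline_meth <= 1")
        if self.region_length <= 0 or self.cpg_mean_spacing <= 0:
            raise UsageError("region_length and cpg_mean_spacing "
                             "must be positive")
        if self.mean_coverage <= 0:
            raise UsageError("mean_coverage must be positive")

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.region_start,
                               self.region_start + self.region_length,
                               name="sim")

    def resolved_alpha(self) -> GenomicInterval:
        if self.alpha_array is not None:
            return self.alpha_array
        length = min(2_000_000, self.region_length)
        mid = self.region_start + self.region_length // 2
        return GenomicInterval(self.chrom, mid - length // 2,
                               mid + length - length // 2)


def _place_dips(params: SimParams,
                rng: np.random.Generator) -> list[GenomicInterval]:
    alpha = params.resolved_alpha()
    margin = params.edge_ramp // 2
    if params.dip_intervals is not None:
        dips = [GenomicInterval(params.chrom, s, e, name=f"dip{i + 1}")
                for i, (s, e) in enumerate(sorted(params.dip_intervals))]
        _check_placement(dips, alpha, margin, params.edge_ramp)
        return dips
    if params.n_dips == 0:
        return []
    lo_len, hi_len = params.dip_length_range
    if lo_len > hi_len or lo_len <= 0:
        raise UsageError("invalid dip_length_range")
    min_gap = params.edge_ramp + 10_000  # keep ramps and calls separable
    for _ in range(1000):
        lengths = rng.integers(lo_len, hi_len + 1, size=params.n_dips)
        starts = rng.integers(alpha.start + margin,
                              max(alpha.start + margin + 1,
                                  alpha.end - margin - int(lengths.max())),
                              size=params.n_dips)
        dips = sorted((int(s), int(s + l))
                      for s, l in zip(starts, lengths))
        try:
            intervals = [GenomicInterval(params.chrom, s, e,
                                         name=f"dip{i + 1}")
                         for i, (s, e) in enumerate(dips)]
            _check_placement(intervals, alpha, margin, min_gap)
        except GenerationError:
            continue
        return intervals
    raise GenerationError(
        f"could not place {params.n_dips} non-overlapping dips inside "
        f"alpha array {alpha} after 1000 attempts")


def _check_placement(dips: Sequence[GenomicInterval],
                     alpha: GenomicInterval, margin: int,
                     min_gap: int) -> None:
    for d in dips:
        if d.start - margin < alpha.start or d.end + margin > alpha.end:
            raise GenerationError(
                f"dip {d} (ramp margin {margin} bp) extends outside "
                f"alpha array {alpha}")
    for a, b in zip(dips, dips[1:]):
        if b.start - a.end < min_gap:
            raise GenerationError(
                f"dips {a} and {b} closer than {min_gap} bp")


def methylation_landscape(params: SimParams,
                          dips: Sequence[GenomicInterval],
                          positions: np.ndarray) -> np.ndarray:
    """True per-position methylation probability.

    Baseline everywhere, ``dip_meth`` inside each dip, with a linear ramp
    of total width ``edge_ramp`` centred on each dip edge.
    """
    half = params.edge_ramp / 2.0
    xp: list[float] = []
    fp: list[float] = []
    for d in dips:
        xp.extend([d.start - half, d.start + half, d.end - half,
                   d.end + half])
        fp.extend([params.baseline_meth, params.dip_meth, params.dip_meth,
                   params.baseline_meth])
    if not xp:
        return np.full(len(positions), params.baseline_meth)
    return np.interp(positions, xp, fp)


def simulate_region(params: SimParams) -> tuple[
        list[MethylRecord], list[RepeatAnnotation], list[GenomicInterval]]:
    """Generate (records, annotations, truth) for one synthetic region."""
    rng = np.random.default_rng(params.seed)
    dips = _place_dips(params, rng)
    region = params.region
    alpha = params.resolved_alpha()

    # CpG positions: geometric gaps, mean = cpg_mean_spacing
    n_expect = int(params.region_length / params.cpg_mean_spacing)
    gaps = rng.geometric(1.0 / params.cpg_mean_spacing,
                         size=int(1.3 * n_expect) + 100)
    positions = region.start + np.cumsum(gaps)
    positions = positions[positions < region.end]

    p = methylation_landscape(params, dips, positions)
    cov = rng.poisson(params.mean_coverage, size=len(positions))
    keep = cov > 0  # zero-coverage sites carry no frequency
    positions, p, cov = positions[keep], p[keep], cov[keep]
    n_mod = rng.binomial(cov, p)

    records = [
        MethylRecord(chrom=params.chrom, start=int(pos), end=int(pos) + 1,
                     mod_code="m", strand=".", valid_cov=int(c),
                     n_mod=int(m), freq=float(m / c))
        for pos, c, m in zip(positions, cov, n_mod)]

    annotations = [RepeatAnnotation(interval=alpha, repeat_name="ALR/Alpha",
                                    repeat_class="Satellite")]
    if alpha.start > region.start:
        annotations.insert(0, RepeatAnnotation(
            interval=GenomicInterval(params.chrom, region.start, alpha.start),
            repeat_name="HSAT", repeat_class="Satellite"))
    if alpha.end < region.end:
        annotations.append(RepeatAnnotation(
            interval=GenomicInterval(params.chrom, alpha.end, region.end),
            repeat_name="other", repeat_class="other"))
    return records, annotations, dips


def split_records_by_strand(records: Sequence[MethylRecord],
                            seed: int = 0) -> list[MethylRecord]:
    """Split combined CpG records into per-strand '+'/'-' row pairs.

    Coverage and methylated counts are partitioned binomially (p = 0.5);
    useful for exercising :func:`cdrscan.io.merge_strand_records`.
    """
    rng = np.random.default_rng(seed)
    out: list[MethylRecord] = []
    for rec in records:
        cov_plus = int(rng.binomial(rec.valid_cov, 0.5))
        cov_minus = rec.valid_cov - cov_plus
        mod_plus = int(rng.hypergeometric(rec.n_mod,
                                          rec.valid_cov - rec.n_mod,
                                          cov_plus)) if cov_plus else 0
        mod_minus = rec.n_mod - mod_plus
        if cov_plus:
            out.append(MethylRecord(
                chrom=rec.chrom, start=rec.start, end=rec.start + 1,
                mod_code=rec.mod_code, strand="+", valid_cov=cov_plus,
                n_mod=mod_plus, freq=mod_plus / cov_plus))
        if cov_minus:
            out.append(MethylRecord(
                chrom=rec.chrom, start=rec.start + 1, end=rec.start + 2,
                mod_code=rec.mod_code, strand="-", valid_cov=cov_minus,
                n_mod=mod_minus, freq=mod_minus / cov_minus))
    return out


def write_fixture(records: Sequence[MethylRecord],
                  annotations: Sequence[RepeatAnnotation],
                  truth: Sequence[GenomicInterval],
                  out_dir: str | Path,
                  region: GenomicInterval | None = None) -> dict[str, Path]:
    """Write a complete on-disk fixture set readable by :mod:`cdrscan.io`.

    Produces ``methylation.bedmethyl``, ``repeats.bed``, ``truth.bed`` and
    ``region.bed`` under *out_dir* and returns their paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bedmethyl": out_dir / "methylation.bedmethyl",
        "repeats": out_dir / "repeats.bed",
        "truth": out_dir / "truth.bed",
        "region": out_dir / "region.bed",
    }
    with open(paths["bedmethyl"], "w") as fh:
        for r in records:
            percent = f"{100.0 * r.freq:.2f}"
            fh.write("\t".join(map(str, [
                r.chrom, r.start, r.end, r.mod_code, r.valid_cov, r.strand,
                r.start, r.end, "0,0,0", r.valid_cov, percent, r.n_mod,
            ])) + "\n")
    with open(paths["repeats"], "w") as fh:
        for a in annotations:
            iv = a.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{a.repeat_name}"
                     f"\t{a.repeat_class}\n")
    write_interval_bed(truth, paths["truth"])
    if region is None and records:
        chrom = records[0].chrom
        region = GenomicInterval(chrom, min(r.start for r in records),
                                 max(r.end for r in records))
    if region is not None:
        write_interval_bed([region], paths["region"])
    return paths


__all__ = ["SimParams", "simulate_region", "write_fixture",
           "split_records_by_strand", "methylation_landscape"]
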