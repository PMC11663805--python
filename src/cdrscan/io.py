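"""Readers and writers for the on-disk formats the tool touches.

All internal coordinates are 0-based half-open (BED convention).
RepeatMasker ``.out`` coordinates (1-based inclusive) are converted on
read.  Methylation is stored as a fraction in [0, 1]; the bedMethyl
percent column is divided by 100 on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import EmptyRegionError, NoRegionsError, ParseError, UsageError

log = logging.getLogger(__name__)

#: modification code for 5-methylcytosine in bedMethyl files
MOD_5MC = "m"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one sequence."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class MethylRecord:
    """One CpG site's pileup row."""

    chrom: str
    start: int
    end: int
    mod_code: str
    strand: str
    valid_cov: int
    n_mod: int
    freq: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_mod <= self.valid_cov):
            raise ValueError(
                f"n_mod={self.n_mod} outside [0, valid_cov={self.valid_cov}]"
                f" at {self.chrom}:{self.start}")
        if not (0.0 <= self.freq <= 1.0):
            raise ValueError(f"freq={self.freq} outside [0, 1]")


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat-annotation interval (e.g. an ALR/Alpha block)."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str = ""


@dataclass(frozen=True)
class CdrCall:
    """One detected hypomethylation dip."""

    interval: GenomicInterval
    min_freq: float
    prominence: float
    seed_bin_index: int
    region_median: float
    region_mean: float
    region_sd: float


# ---------------------------------------------------------------------------
# bedMethyl


def _split_bedmethyl_row(line: str) -> list[str]:
    # Tab-delimited is canonical; one common dialect packs columns 10+ as a
    # single space-delimited tab field, and hand-written fixtures may be
    # fully space-delimited.
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        fields = line.split()
    elif len(fields) == 10:
        fields = fields[:9] + fields[9].split()
    return fields


def read_bedmethyl(path: str | Path,
                   regions: Sequence[GenomicInterval]) -> list[MethylRecord]:
    """Read a bedMethyl pileup, keeping 5mC records overlapping *regions*.

    Tolerates both the "simple" (>=12 column) and extended (18 column)
    dialects, including the variant that space-packs columns 10+ into the
    tenth tab field.  Records whose modification code is not ``"m"`` are
    dropped with a logged count.

    Raises
    ------
    ParseError
        On malformed rows (naming the line number).
    EmptyRegionError
        If any requested region has no overlapping record.
    """
    if not regions:
        raise UsageError("read_bedmethyl requires at least one region")
    path = Path(path)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    records: list[MethylRecord] = []
    n_dropped_mod = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = _split_bedmethyl_row(line)
            if len(fields) < 10:
                raise ParseError(
                    f"bedMethyl row has {len(fields)} columns, expected >= 10",
                    path=str(path), line_number=lineno)
            chrom = fields[0]
            chrom_regions = by_chrom.get(chrom)
            if not chrom_regions:
                continue
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}",
                    path=str(path), line_number=lineno) from None
            if not any(r.start < end and start < r.end for r in chrom_regions):
                continue
            mod_code = fields[3]
            if mod_code != MOD_5MC:
                n_dropped_mod += 1
                continue
            strand = fields[5] if len(fields) > 5 else "."
            try:
                valid_cov = int(fields[9])
                percent = float(fields[10])
                n_mod = int(fields[11]) if len(fields) > 11 else round(
                    valid_cov * percent / 100.0)
            except (ValueError, IndexError):
                raise ParseError(
                    "malformed coverage/percent/count columns",
                    path=str(path), line_number=lineno) from None
            if not (0.0 <= percent <= 100.0):
                raise ParseError(
                    f"percent_modified {percent} outside [0, 100]",
                    path=str(path), line_number=lineno)
            try:
                records.append(MethylRecord(
                    chrom=chrom, start=start, end=end, mod_code=mod_code,
                    strand=strand, valid_cov=valid_cov, n_mod=n_mod,
                    freq=percent / 100.0))
            except ValueError as exc:
                raise ParseError(str(exc), path=str(path),
                                 line_number=lineno) from None

    if n_dropped_mod:
        log.info("dropped %d non-5mC modification rows", n_dropped_mod)
    records.sort(key=lambda r: (r.chrom, r.start))
    for region in regions:
        if not any(r.chrom == region.chrom
                   and r.start < region.end and region.start < r.end
                   for r in records):
            raise EmptyRegionError(region)
    return records


def merge_strand_records(records: Sequence[MethylRecord]) -> list[MethylRecord]:
    """Collapse per-strand rows of one CpG dinucleotide into one record.

    A ``+`` row at position *p* and a ``-`` row at *p + 1* on the same
    sequence are summed (``valid_cov``, ``n_mod``) and the frequency is
    recomputed.  Already-combined records pass through unchanged.  Total
    coverage and methylated counts are conserved.
    """
    merged: list[MethylRecord] = []
    i = 0
    n = len(records)
    while i < n:
        rec = records[i]
        if (rec.strand == "+" and i + 1 < n):
            nxt = records[i + 1]
            if (nxt.strand == "-" and nxt.chrom == rec.chrom
                    and nxt.start == rec.start + 1):
                cov = rec.valid_cov + nxt.valid_cov
                mod = rec.n_mod + nxt.n_mod
                merged.append(MethylRecord(
                    chrom=rec.chrom, start=rec.start, end=rec.start + 2,
                    mod_code=rec.mod_code, strand=".",
                    valid_cov=cov, n_mod=mod,
                    freq=(mod / cov) if cov > 0 else 0.0))
                i += 2
                continue
        merged.append(rec)
        i += 1
    return merged


# ---------------------------------------------------------------------------
# BED


def read_region_bed(path: str | Path) -> list[GenomicInterval]:
    """Read target regions from a BED3+ file, in file order."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError("BED row has fewer than 3 columns",
                                 path=str(path), line_number=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}",
                    path=str(path), line_number=lineno) from None
            if start >= end:
                raise ParseError(
                    f"degenerate interval {fields[0]}:{start}-{end}",
                    path=str(path), line_number=lineno)
            name = fields[3] if len(fields) > 3 else None
            intervals.append(GenomicInterval(fields[0], start, end, name=name))
    if not intervals:
        raise NoRegionsError(f"no regions found in {path}")
    return intervals


# ---------------------------------------------------------------------------
# repeat annotations


def read_repeat_annotation(path: str | Path,
                           dialect: str = "bed") -> list[RepeatAnnotation]:
    """Read a repeat annotation in BED4+ or RepeatMasker ``.out`` layout.

    Every annotation is returned; restriction to "ALR/Alpha" happens
    downstream.  ``rmout`` query coordinates (1-based inclusive) are
    shifted to 0-based half-open.
    """
    if dialect == "bed":
        return _read_repeat_bed(path)
    if dialect == "rmout":
        return _read_repeat_rmout(path)
    raise UsageError(f"unknown repeat-annotation dialect {dialect!r} "
                     "(expected 'bed' or 'rmout')")


def _read_repeat_bed(path: str | Path) -> list[RepeatAnnotation]:
    path = Path(path)
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(
                    "repeat BED row needs >= 4 columns (4th = repeat name)",
                    path=str(path), line_number=lineno)
            try:
                interval = GenomicInterval(fields[0], int(fields[1]),
                                           int(fields[2]))
            except ValueError as exc:
                raise ParseError(str(exc), path=str(path),
                                 line_number=lineno) from None
            repeat_class = fields[4] if len(fields) > 4 else ""
            annotations.append(RepeatAnnotation(
                interval=interval, repeat_name=fields[3],
                repeat_class=repeat_class))
    return annotations


def _read_repeat_rmout(path: str | Path) -> list[RepeatAnnotation]:
    path = Path(path)
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue  # 3 header lines, blank separators
            fields = line.split()
            if len(fields) < 15:
                raise ParseError(
                    f"RepeatMasker row has {len(fields)} columns, "
                    "expected >= 15",
                    path=str(path), line_number=lineno)
            try:
                qbegin = int(fields[5])
                qend = int(fields[6])
            except ValueError:
                raise ParseError(
                    f"non-integer query coordinates {fields[5]!r}, "
                    f"{fields[6]!r}",
                    path=str(path), line_number=lineno) from None
            try:
                interval = GenomicInterval(fields[4], qbegin - 1, qend)
            except ValueError as exc:
                raise ParseError(str(exc), path=str(path),
                                 line_number=lineno) from None
            annotations.append(RepeatAnnotation(
                interval=interval, repeat_name=fields[9],
                repeat_class=fields[10]))
    return annotations


# ---------------------------------------------------------------------------
# output


def write_cdr_bed(calls: Sequence[CdrCall], path: str | Path) -> Path:
    """Write dip calls as BED, score = ``min_freq`` scaled to 0-1000.

    Calls are written as given (no merging at write time); an empty call
    list yields an empty, header-free file.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for call in calls:
            iv = call.interval
            name = iv.name or "CDR"
            score = round(call.min_freq * 1000)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")
    return path


def write_interval_bed(intervals: Iterable[GenomicInterval],
                       path: str | Path) -> Path:
    """Write plain intervals as BED3/BED4 (used for truth/region files)."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return path


__all__ = [
    "GenomicInterval", "MethylRecord", "RepeatAnnotation", "CdrCall",
    "read_bedmethyl", "merge_strand_records", "read_region_bed",
    "read_repeat_annotation", "write_cdr_bed", "write_interval_bed",
    "MOD_5MC",
]
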