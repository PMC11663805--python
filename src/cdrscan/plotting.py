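"""Per-region diagnostic figure.

Three vertically stacked panels sharing the genomic x-axis: repeat
annotation blocks with a bar over each dip call (top), per-bin mean CpG
methylation with the regional median as a reference line (middle), and
per-bin mean total / methylated read coverage (bottom).  Call spans are
shaded in every panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.figure import Figure

from .binning import ALPHA_REPEAT_NAME, BinnedProfile
from .errors import UsageError
from .io import CdrCall, GenomicInterval, RepeatAnnotation

SUPPORTED_FORMATS = ("png", "svg", "pdf")

# default palette keyed by repeat name; alpha-satellite kept visually distinct
_REPEAT_COLORS = {
    ALPHA_REPEAT_NAME: "#d62728",
    "HSAT": "#1f77b4",
    "HSat2": "#1f77b4",
    "HSat3": "#17becf",
    "BSR/Beta": "#9467bd",
}
_FALLBACK_COLOR = "#7f7f7f"
_SHADE_COLOR = "#fdd9a0"


@dataclass
class TrackFigureSpec:
    region: GenomicInterval
    profile: BinnedProfile
    annotations: Sequence[RepeatAnnotation]
    calls: Sequence[CdrCall]
    output_path: str | Path
    image_format: str = "png"


def build_region_figure(spec: TrackFigureSpec) -> Figure:
    """Assemble the three-panel figure without writing it to disk."""
    if not spec.profile.bins:
        raise UsageError("cannot plot an empty profile")
    region = spec.region
    fig, (ax_anno, ax_meth, ax_cov) = plt.subplots(
        3, 1, sharex=True, figsize=(12, 7),
        gridspec_kw={"height_ratios": [1, 2, 2]})

    # --- top: repeat annotation + call bars
    seen_names: list[str] = []
    for anno in spec.annotations:
        if anno.interval.chrom != region.chrom:
            continue
        color = _REPEAT_COLORS.get(anno.repeat_name, _FALLBACK_COLOR)
        label = None
        if anno.repeat_name not in seen_names:
            seen_names.append(anno.repeat_name)
            label = anno.repeat_name
        ax_anno.broken_barh(
            [(anno.interval.start, anno.interval.length)], (0.0, 0.55),
            facecolors=color, label=label)
    for call in spec.calls:
        ax_anno.broken_barh(
            [(call.interval.start, call.interval.length)], (0.7, 0.25),
            facecolors="black", label=None)
    ax_anno.set_ylim(0, 1)
    ax_anno.set_yticks([])
    ax_anno.set_ylabel("repeats")
    if seen_names:
        ax_anno.legend(loc="upper right", fontsize=7, ncol=min(4,
                       len(seen_names)), frameon=False)

    # --- middle: binned methylation (invalid bins blank)
    centers = np.array([(b.interval.start + b.interval.end) / 2
                        for b in spec.profile.bins])
    freqs = np.array([b.mean_freq if b.is_valid else np.nan
                      for b in spec.profile.bins], dtype=float)
    ax_meth.plot(centers, freqs, lw=0.8, color="#333333")
    if spec.calls:
        ax_meth.axhline(spec.calls[0].region_median, ls="--", lw=0.8,
                        color="#d62728", label="alpha-bin median")
        ax_meth.legend(loc="upper right", fontsize=7, frameon=False)
    ax_meth.set_ylim(0, 1)
    ax_meth.set_ylabel("mean CpG\nmethylation")

    # --- bottom: coverage
    total = np.array([b.mean_valid_cov if b.is_valid else np.nan
                      for b in spec.profile.bins], dtype=float)
    meth = np.array([b.mean_mod_cov if b.is_valid else np.nan
                     for b in spec.profile.bins], dtype=float)
    ax_cov.plot(centers, total, lw=0.8, color="#1f77b4", label="total")
    ax_cov.plot(centers, meth, lw=0.8, color="#d62728", label="methylated")
    ax_cov.set_ylabel("mean read\ncoverage")
    ax_cov.set_ylim(bottom=0)
    ax_cov.legend(loc="upper right", fontsize=7, frameon=False)
    ax_cov.set_xlabel(f"{region.chrom} position (bp)")

    # --- shade call spans on every panel
    for ax in (ax_anno, ax_meth, ax_cov):
        for call in spec.calls:
            ax.axvspan(call.interval.start, call.interval.end,
                       color=_SHADE_COLOR, alpha=0.6, zorder=0,
                       label="_cdr_span")
    ax_cov.set_xlim(region.start, region.end)
    fig.suptitle(str(region), fontsize=10)
    fig.tight_layout()
    return fig


def render_region_plot(spec: TrackFigureSpec) -> Path:
    """Write the figure to ``spec.output_path``; returns the path."""
    if spec.image_format not in SUPPORTED_FORMATS:
        raise UsageError(
            f"unknown image format {spec.image_format!r}; "
            f"expected one of {SUPPORTED_FORMATS}")
    fig = build_region_figure(spec)
    path = Path(spec.output_path)
    try:
        fig.savefig(path, format=spec.image_format, dpi=150)
    finally:
        plt.close(fig)
    return path


def region_plot_filename(sample: str, region: GenomicInterval,
                         image_format: str) -> str:
    return (f"{sample}_{region.chrom}_{region.start}_{region.end}"
            f".{image_format}")


__all__ = ["TrackFigureSpec", "build_region_figure", "render_region_plot",
           "region_plot_filename", "SUPPORTED_FORMATS"]
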