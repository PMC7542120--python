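"""Static renderings of the segmentation statistics.

Three plot families: code-frequency bar charts, paired log-scaled length
histograms, and heatmaps with three palette conventions — sequential pink
for raw counts, blue-under/red-over diverging for observed-vs-expected
log-odds, and red-positive/blue-negative diverging for correlations.
Absent cells (no pairs observed or expected) render black so they are
distinguishable from near-white small values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering only

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap, Normalize, TwoSlopeNorm

from .segstats import CodeFrequency, LengthHistogram

__all__ = ["HeatmapSpec", "plot_code_frequency", "plot_length_histograms", "plot_heatmap"]

PALETTES = ("sequential-pink", "diverging-red-blue", "diverging-blue-red")

_PINK = LinearSegmentedColormap.from_list("seqpink", ["#ffffff", "#e3007f"])
# red-blue: negative -> red, positive -> blue (observed-vs-expected convention)
_RED_BLUE = LinearSegmentedColormap.from_list("divrb", ["#d7191c", "#ffffff", "#2c7bb6"])
# blue-red: negative -> blue, positive -> red (correlation convention)
_BLUE_RED = LinearSegmentedColormap.from_list("divbr", ["#2c7bb6", "#ffffff", "#d7191c"])


@dataclass
class HeatmapSpec:
    """A matrix plus the palette and transform rules to render it."""

    matrix: np.ndarray
    row_labels: Sequence
    col_labels: Sequence
    palette: str = "sequential-pink"
    value_transform: str = "identity"  # or "log10p1"
    title: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.palette not in PALETTES:
            raise ValueError(f"palette must be one of {PALETTES}")
        if self.value_transform not in ("identity", "log10p1"):
            raise ValueError("value_transform must be 'identity' or 'log10p1'")

    def transformed(self) -> np.ndarray:
        if self.value_transform == "log10p1":
            return np.log10(1.0 + self.matrix)
        return self.matrix.copy()


def plot_code_frequency(
    freq: CodeFrequency, path: str | Path | None = None, labels: dict[int, str] | None = None
):
    """Bar chart: one bar per code in numeric order, height = frequency."""
    n_codes = freq.n_codes or (max(freq.counts, default=0) + 1)
    codes = list(range(n_codes))
    heights = [freq.counts.get(c, 0) for c in codes]
    fig, ax = plt.subplots(figsize=(max(4, n_codes * 0.8), 4))
    ax.bar(codes, heights, color="#4c72b0")
    ticklabels = [
        f"{c}\n{labels[c]}" if labels and c in labels else str(c) for c in codes
    ]
    ax.set_xticks(codes, ticklabels)
    ax.set_xlabel("code")
    ax.set_ylabel("segment count")
    ax.set_title(f"Code frequency ({freq.scope})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig, ax


def plot_length_histograms(
    pairs: Sequence[tuple[LengthHistogram, LengthHistogram]],
    path: str | Path | None = None,
):
    """Grouped two-color bars per bin, frequency axis log-scaled.

    Zero-count bins are drawn as absent (log scale cannot show them).
    """
    if not pairs:
        raise ValueError("no histogram pairs to plot")
    for a, b in pairs:
        if a.bin_width != b.bin_width:
            raise ValueError("mismatched bin grids within a pair")
    fig, axes = plt.subplots(
        len(pairs), 1, figsize=(8, 3 * len(pairs)), squeeze=False
    )
    for ax, (a, b) in zip(axes[:, 0], pairs):
        w = a.bin_width
        kmax = max(max(a.counts, default=0), max(b.counts, default=0))
        xs = np.arange(kmax + 1) * w
        ha = np.array([a.counts.get(k, 0) for k in range(kmax + 1)], dtype=float)
        hb = np.array([b.counts.get(k, 0) for k in range(kmax + 1)], dtype=float)
        ha[ha == 0] = np.nan  # absent on log axis
        hb[hb == 0] = np.nan
        bar_w = w * 0.4
        ax.bar(xs, ha, width=bar_w, align="edge", color="#8172b3", label=a.series_label)
        ax.bar(xs + bar_w, hb, width=bar_w, align="edge", color="#55a868", label=b.series_label)
        ax.set_yscale("log")
        ax.set_xlabel("length (nt)")
        ax.set_ylabel("count")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig, axes[:, 0].tolist()


def plot_heatmap(spec: HeatmapSpec, path: str | Path | None = None):
    """Render a heatmap per the palette rules; absent (NaN) cells are black.

    Sequential palette maps 0 to white and the matrix maximum to full
    saturation; diverging palettes centre at 0 (white) and saturate at the
    largest absolute value.  Non-finite values other than NaN are an error.
    """
    data = spec.transformed()
    if np.any(np.isinf(data)):
        raise ValueError("non-finite values other than the absent sentinel (NaN)")
    masked = np.ma.masked_invalid(data)
    if spec.palette == "sequential-pink":
        vmax = float(masked.max()) if masked.count() else 1.0
        norm = Normalize(vmin=0.0, vmax=vmax if vmax > 0 else 1.0)
        cmap = _PINK
    else:
        bound = float(np.abs(masked).max()) if masked.count() else 1.0
        bound = bound if bound > 0 else 1.0
        norm = TwoSlopeNorm(vmin=-bound, vcenter=0.0, vmax=bound)
        cmap = _RED_BLUE if spec.palette == "diverging-red-blue" else _BLUE_RED
    cmap = cmap.copy()
    cmap.set_bad("black")

    nrow, ncol = data.shape
    fig, ax = plt.subplots(figsize=(max(4, ncol * 0.6), max(3, nrow * 0.5)))
    im = ax.imshow(masked, cmap=cmap, norm=norm, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(ncol), [str(c) for c in spec.col_labels], rotation=90, fontsize=8)
    ax.set_yticks(range(nrow), [str(r) for r in spec.row_labels], fontsize=8)
    if spec.title:
        ax.set_title(spec.title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig, ax
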