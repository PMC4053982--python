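"""Diagnostic figures: segment scatter and per-chromosome profiles.

The scatter of allelic imbalance ratio against normalized coverage is
the primary interpretive view: clusters of segments are copy-number
states, and their spacing encodes ploidy and tumor cell content.  One
chromosome can be highlighted with a positional color gradient from
blue (distal p arm) to red (distal q arm) while the rest of the genome
stays grey; point area scales with segment length.

Rendering is deterministic (fixed canvas, no timestamps) and
data-faithful: the plotted coordinates are exactly the segment table's
columns, which the tests verify through matplotlib's object model.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

__all__ = ["plot_scatter", "plot_profile"]

_GRADIENT = LinearSegmentedColormap.from_list("arm_gradient", ["#2040c0", "#c03030"])


def _point_sizes(segments: pd.DataFrame, max_size: float = 200.0) -> np.ndarray:
    length = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    top = length.max() if len(length) and length.max() > 0 else 1.0
    return 10.0 + (max_size - 10.0) * length / top


def plot_scatter(segments: pd.DataFrame, highlight: str | None = None,
                 path: str | Path | None = None, figsize=(7.0, 5.0)):
    """Allelic imbalance ratio vs normalized coverage, one point per segment.

    Segments without an imbalance ratio are omitted (they have no y
    coordinate).  Returns the matplotlib Figure.
    """
    plotted = segments[np.isfinite(segments["ai_ratio"].to_numpy(dtype=float))
                       & np.isfinite(segments["mean_ratio"].to_numpy(dtype=float))]
    fig, ax = plt.subplots(figsize=figsize)
    bg = plotted if highlight is None else plotted[plotted["chrom"] != highlight]
    ax.scatter(bg["mean_ratio"], bg["ai_ratio"], s=_point_sizes(bg),
               c="#b0b0b0", alpha=0.7, linewidths=0, label="_background")
    if highlight is not None:
        fg = plotted[plotted["chrom"] == highlight]
        if not fg.empty:
            lo = float(fg["start"].min())
            hi = float(fg["end"].max())
            mid = (fg["start"] + fg["end"]).to_numpy(dtype=float) / 2.0
            frac = (mid - lo) / (hi - lo) if hi > lo else np.full(len(fg), 0.5)
            ax.scatter(fg["mean_ratio"], fg["ai_ratio"], s=_point_sizes(fg),
                       c=_GRADIENT(frac), linewidths=0, label=highlight)
    ax.set_xlabel("normalized coverage")
    ax.set_ylabel("allelic imbalance ratio")
    ax.set_ylim(-0.02, 1.02)
    if highlight:
        ax.set_title(highlight)
    if path is not None:
        fig.savefig(path, dpi=100, metadata={"Software": None})
    return fig


def plot_profile(calls: pd.DataFrame, chrom: str, bins: pd.DataFrame | None = None,
                 path: str | Path | None = None, figsize=(8.0, 5.0),
                 continuous: bool = False):
    """Step plot of total/minor copy number along one chromosome.

    The top panel steps through the called total (and, where defined,
    minor) copy number per segment; with ``continuous=True`` the
    coverage-implied non-integer copy number is drawn instead of the
    integer calls (heterogeneous regions).  The bottom panel shows the
    normalized coverage of the underlying bins when given.  Returns the
    Figure.
    """
    sub = calls[calls["chrom"] == chrom].sort_values("start")
    if sub.empty:
        raise ValueError(f"no calls on {chrom}")
    n_panels = 2 if bins is not None else 1
    fig, axes = plt.subplots(n_panels, 1, figsize=figsize, sharex=True, squeeze=False)
    ax = axes[0][0]
    for seg in sub.itertuples(index=False):
        if continuous:
            ax.plot([seg.start, seg.end], [seg.n_continuous, seg.n_continuous],
                    color="#c03030", lw=2)
        else:
            if not pd.isna(seg.total_cn):
                ax.plot([seg.start, seg.end], [seg.total_cn, seg.total_cn],
                        color="#c03030", lw=2.5, solid_capstyle="butt")
            if not pd.isna(seg.minor_cn):
                ax.plot([seg.start, seg.end], [seg.minor_cn, seg.minor_cn],
                        color="#2040c0", lw=2.5, solid_capstyle="butt")
    ax.set_ylabel("copy number")
    ax.set_title(chrom)
    ax.set_ylim(bottom=-0.3)
    if bins is not None:
        axb = axes[1][0]
        sel = bins[bins["chrom"] == chrom]
        axb.scatter(sel["start"], sel["ratio"], s=2, c="#606060", linewidths=0)
        axb.set_ylabel("normalized coverage")
        axb.set_xlabel("position (bp)")
    else:
        ax.set_xlabel("position (bp)")
    if path is not None:
        fig.savefig(path, dpi=100, metadata={"Software": None})
    return fig
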