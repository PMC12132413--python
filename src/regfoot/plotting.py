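"""Figure panels: information footprints and condition-cluster heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .condition_clustering import ConditionMatrix
from .coords import axis_labels
from .footprint_stats import ExpressionShiftMatrix, Footprint


def plot_footprint(fp: Footprint, shifts: ExpressionShiftMatrix | None = None,
                   ax=None):
    """Per-base information footprint, bars colored by expression-shift sign
    (red: mutations increase expression, repressor-like; blue: decrease)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    labels = axis_labels()[: fp.mi.size]
    colors = "gray"
    if shifts is not None:
        mean_shift = np.nanmean(
            np.where(np.isfinite(shifts.shifts), shifts.shifts, np.nan), axis=0)
        colors = ["tab:red" if s > 0 else "tab:blue" for s in mean_shift]
    ax.bar(np.arange(fp.mi.size), fp.mi, color=colors, width=1.0)
    ticks = np.arange(0, fp.mi.size, 20)
    ax.set_xticks(ticks, labels[ticks])
    ax.set_xlabel("position relative to TSS")
    ax.set_ylabel("mutual information (bits)")
    ax.set_title(f"{fp.promoter_id} | {fp.condition} r{fp.replicate}")
    return ax


def plot_condition_heatmap(matrix: ConditionMatrix, ax=None):
    """Global condition x position MI heatmap (rows: condition x replicate)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.3 * len(matrix.row_labels) + 1))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis",
                   interpolation="nearest")
    ax.set_yticks(range(len(matrix.row_labels)),
                  [f"{c} r{r}" for c, r in matrix.row_labels])
    ax.set_xlabel("concatenated promoter positions")
    plt.colorbar(im, ax=ax, label="MI (bits)")
    return ax
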