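"""Static matplotlib renderers for the five plot types.

Rendering is deliberately thin: every number in a figure comes from a
table produced by the analysis modules, so correctness is tested on the
tables and the figures are only smoke-tested.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "render_mountain",
    "render_manhattan",
    "render_deflection",
    "render_volcano",
    "render_beeswarm",
]

#: x-axis slots left blank between arms (the centromere gap)
_ARM_GAP = 5


def _save(fig, path):
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def render_mountain(curves, path, title: str = "Mountain plot") -> None:
    """Scatter per-gene group summaries along the genome, one gap per
    centromere (and per chromosome boundary)."""
    curves = [c for c in curves if not c.is_empty]
    if not curves:
        raise ValueError("no non-empty curves to render")
    fig, ax = plt.subplots(figsize=(max(8, len(curves)), 3))
    x0 = 0
    ticks, labels = [], []
    for c in curves:
        xs = np.arange(x0, x0 + len(c))
        ax.scatter(xs, c.values, s=6)
        ticks.append(x0 + len(c) / 2)
        labels.append(f"{c.chromosome}{c.arm}")
        x0 += len(c) + _ARM_GAP
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.set_xticks(ticks, labels, rotation=90, fontsize=6)
    ax.set_ylabel(f"{curves[0].summary_kind} CNV")
    ax.set_title(title)
    _save(fig, path)


def render_manhattan(stats: pd.DataFrame, path, directional: bool = False) -> None:
    """Per-gene -log10 Q bars; in directional mode bars carry the sign of
    the group-median difference (below the baseline when group 1 is
    lower)."""
    if stats.empty:
        raise ValueError("empty stats table")
    y = stats["neg_log10_q"] * (stats["sign"] if directional else 1)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.vlines(np.arange(len(stats)), 0, y, lw=0.8)
    ax.axhline(0.0, lw=0.5, color="black")
    ax.set_ylabel("signed -log10 Q" if directional else "-log10 Q")
    ax.set_xlabel("genes (genome order)")
    _save(fig, path)


def render_deflection(records: pd.DataFrame, path) -> None:
    """Two-color signed -log10 Q lines; the color of each gene marks the
    cancer type with the comparatively greater deflection."""
    if records.empty:
        raise ValueError("empty deflection table")
    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(records))
    amp = np.where(
        records["winner"] == "type2", records["amplitude2"], records["amplitude1"]
    )
    colors = np.where(records["winner"] == "type2", "tab:orange", "tab:blue")
    ax.vlines(x, 0, amp, colors=colors, lw=0.8)
    ax.axhline(0.0, lw=0.5, color="black")
    ax.set_ylabel("signed -log10 Q")
    ax.set_xlabel("genes (genome order)")
    _save(fig, path)


def render_volcano(records: pd.DataFrame, path, cutoff: float = 0.05) -> None:
    """Fold change vs -log10 p with a dashed horizontal cutoff line."""
    if records.empty:
        raise ValueError("empty volcano table")
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = records["significant"].to_numpy(dtype=bool)
    ax.scatter(
        records["log2_fold_change"][~sig], records["neg_log10_p"][~sig],
        s=8, color="grey",
    )
    ax.scatter(
        records["log2_fold_change"][sig], records["neg_log10_p"][sig],
        s=8, color="tab:red",
    )
    ax.axhline(-np.log10(cutoff), ls="--", lw=0.8, color="black")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    _save(fig, path)


def render_beeswarm(values, offsets, path, boxplot: bool = False) -> None:
    """One-dimensional packed scatter of values with optional box overlay."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    fig, ax = plt.subplots(figsize=(3, 4))
    if boxplot:
        ax.boxplot(values, positions=[0.0], widths=0.6, showfliers=False)
    ax.scatter(np.asarray(offsets, dtype=float), values, s=10, zorder=3)
    ax.set_xticks([])
    ax.set_ylabel("value")
    _save(fig, path)
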