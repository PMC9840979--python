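"""Figure helpers: ethogram rasters, effect heatmaps, paired contrast plots.

All functions return the matplotlib Figure and optionally save it; they are
deliberately thin wrappers so the numbers always come from the analysis
modules.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ethogram import ACTIVE, Ethogram

__all__ = ["raster_plot", "effect_heatmap", "paired_plot", "duration_histogram_plot"]


def _save(fig, path):
    if path is not None:
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
    return fig


def raster_plot(
    ethograms: list[Ethogram],
    flash_time: float | None = None,
    path: str | Path | None = None,
):
    """Activity raster, one row per fly; if ``flash_time`` is given the time
    axis is re-zeroed at the light onset."""
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(ethograms) + 1.2))
    shift = flash_time or 0.0
    for i, eth in enumerate(ethograms):
        for e in eth.epochs:
            if e.state == ACTIVE:
                ax.broken_barh(
                    [(e.start - shift, e.duration)], (i - 0.4, 0.8), color="k"
                )
    if flash_time is not None:
        ax.axvline(0.0, color="r", lw=1.5, label="light on")
        ax.legend(loc="upper right", frameon=False)
    ax.set_xlabel("time (s)" + (" relative to light onset" if flash_time else ""))
    ax.set_ylabel("fly")
    ax.set_yticks(range(len(ethograms)))
    ax.set_ylim(-0.6, len(ethograms) - 0.4)
    return _save(fig, path)


def effect_heatmap(
    d_matrix: pd.DataFrame,
    marks: pd.DataFrame,
    path: str | Path | None = None,
    vlim: float = 1.5,
):
    """Annotated Cohen's d heatmap; asterisks mark cells with p < alpha."""
    fig, ax = plt.subplots(
        figsize=(1.1 * d_matrix.shape[1] + 2, 0.6 * d_matrix.shape[0] + 1.5)
    )
    im = ax.imshow(d_matrix.to_numpy(dtype=float), cmap="RdBu_r", vmin=-vlim, vmax=vlim)
    ax.set_xticks(range(d_matrix.shape[1]), d_matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(d_matrix.shape[0]), d_matrix.index)
    for i in range(d_matrix.shape[0]):
        for j in range(d_matrix.shape[1]):
            v = d_matrix.iat[i, j]
            if np.isnan(v):
                continue
            star = "*" if bool(marks.iat[i, j]) else ""
            ax.text(j, i, f"{v:.2f}{star}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Cohen's d")
    return _save(fig, path)


def paired_plot(
    before: np.ndarray,
    after: np.ndarray,
    ci95: tuple[float, float] | None = None,
    labels: tuple[str, str] = ("before", "after"),
    path: str | Path | None = None,
):
    """Slopegraph of paired values with the mean-difference interval below."""
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(4, 6), height_ratios=[3, 1], sharex=False
    )
    for b, a in zip(before, after):
        ax0.plot([0, 1], [b, a], color="gray", alpha=0.4, lw=0.8)
    ax0.plot([0, 1], [before.mean(), after.mean()], color="k", lw=2)
    ax0.set_xticks([0, 1], labels)
    ax0.set_xlim(-0.3, 1.3)
    diff = (after - before).mean()
    ax1.axhline(0, color="gray", lw=0.8)
    ax1.plot([0], [diff], "ko")
    if ci95 is not None:
        ax1.vlines(0, ci95[0], ci95[1], color="k", lw=2)
    ax1.set_xticks([0], ["mean difference"])
    ax1.set_xlim(-0.5, 0.5)
    fig.tight_layout()
    return _save(fig, path)


def duration_histogram_plot(
    hist: dict[str, tuple[np.ndarray, np.ndarray]],
    path: str | Path | None = None,
):
    """Per-state epoch-duration distributions (probability per bin)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for state, (edges, probs) in hist.items():
        ax.stairs(probs, edges, label=state, fill=False, lw=1.5)
    ax.axvline(5.0, color="gray", ls="--", lw=1, label="immobility rule (5 s)")
    ax.set_xlabel("epoch duration (s)")
    ax.set_ylabel("probability")
    ax.legend(frameon=False)
    return _save(fig, path)
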