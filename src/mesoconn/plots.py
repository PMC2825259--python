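"""Figure analogues: z-P role plane, cost-efficiency frontier, heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cartography import RoleThresholds
from .cost import CostPoint, bin_frontier

__all__ = ["plot_zp_plane", "plot_frontier", "plot_matrix_heatmap"]


def plot_zp_plane(
    records: pd.DataFrame,
    path: str | Path,
    thresholds: RoleThresholds | None = None,
) -> Path:
    """Scatter of within-module degree z against participation P with the
    seven role regions shaded."""
    th = thresholds or RoleThresholds()
    fig, ax = plt.subplots(figsize=(6, 5))
    z_lo = min(-1.5, records["z"].min() - 0.5)
    z_hi = max(4.0, records["z"].max() + 0.5)
    cuts_n = [0.0, *th.nonhub_p, 1.0]
    cuts_h = [0.0, *th.hub_p, 1.0]
    shades = ["#dddddd", "#cfe2ff", "#ffd6e7", "#d2f5d2"]
    for lo, hi, c in zip(cuts_n[:-1], cuts_n[1:], shades):
        ax.axvspan(lo, hi, ymin=0, ymax=(th.z_hub - z_lo) / (z_hi - z_lo), color=c, alpha=0.5)
    for lo, hi, c in zip(cuts_h[:-1], cuts_h[1:], ["#fff3bf", "#ffc9c9", "#ffffff"]):
        ax.axvspan(lo, hi, ymin=(th.z_hub - z_lo) / (z_hi - z_lo), ymax=1, color=c, alpha=0.5)
    ax.axhline(th.z_hub, color="k", lw=0.8)
    ax.scatter(records["P"], records["z"], s=12, c="k", zorder=3)
    ax.set_xlim(0, 1)
    ax.set_ylim(z_lo, z_hi)
    ax.set_xlabel("participation coefficient P")
    ax.set_ylabel("within-module degree z")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_frontier(points: list[CostPoint], path: str | Path, n_bins: int = 20) -> Path:
    """Efficiency against wiring cost: binned randomized ensemble (mean and
    sd per bin) with the empirical network marked by a cross."""
    binned = bin_frontier(points, n_bins=n_bins)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, model in zip(axes, ("DW", "CW")):
        sub = binned[binned["model"] == model]
        ax.errorbar(sub["cost_mid"], sub["eff_mean"], yerr=sub["eff_sd"], fmt="o-", ms=3)
        for p in points:
            if p.source == "empirical" and p.model == model:
                ax.plot(p.cost, p.efficiency, "rx", ms=10, mew=2)
        ax.set_xlabel(f"wiring cost ({model})")
        ax.set_title(model)
    axes[0].set_ylabel("efficiency E")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_matrix_heatmap(
    matrix: pd.DataFrame, path: str | Path, title: str = "", cmap: str = "viridis"
) -> Path:
    """Labelled heatmap of any square matrix (density, lineage, roles)."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    data = matrix.to_numpy(dtype=float)
    im = ax.imshow(data, cmap=cmap)
    ax.set_xticks(np.arange(len(matrix.columns)), labels=[str(c) for c in matrix.columns])
    ax.set_yticks(np.arange(len(matrix.index)), labels=[str(i) for i in matrix.index])
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
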