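"""Figures and per-participant activation videos.

Videos are rendered as a directory of PNG frames (one per 100 ms bin) on
the schematic 2-D parcel layout, so tests can assert on frame counts and
the data behind them without any codec dependency. All plotting uses the
Agg backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .activation import ActivationMap, SpreadSeries
from .layout import ParcelLayout

__all__ = ["plot_spread_timecourse", "region_activation_proportion",
           "plot_region_map", "render_activation_frames"]


def plot_spread_timecourse(spreads: Sequence[SpreadSeries], band: str,
                           window: tuple[float, float] = (1.0, 3.0),
                           out: str | Path | None = None):
    """Group-mean +/- SD activated / deactivated region counts over time.

    Returns (fig, data) where data maps '<group>:<kind>' to the plotted
    group-mean arrays, so numerical checks never re-read pixels.
    """
    groups = sorted({s.group for s in spreads})
    centers = spreads[0].bin_centers()
    bi = spreads[0].band_index(band)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    data = {}
    colors = {"HC": "tab:blue", "ALS": "tab:red"}
    for ax, kind in zip(axes, ("activated", "deactivated")):
        for g in groups:
            stack = np.stack([getattr(s, f"{kind}_count")[bi]
                              for s in spreads if s.group == g])
            mu, sd = stack.mean(axis=0), stack.std(axis=0)
            data[f"{g}:{kind}"] = mu
            ax.plot(centers, mu, label=g, color=colors.get(g))
            ax.fill_between(centers, mu - sd, mu + sd, alpha=0.2,
                            color=colors.get(g))
        ax.axvspan(*window, color="gray", alpha=0.15, label="tonic grip")
        ax.set_xlabel("time from trigger (s)")
        ax.set_title(f"{band} {kind} regions")
    axes[0].set_ylabel("region count (trial mean)")
    axes[0].legend()
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=110)
        plt.close(fig)
    return fig, data


def region_activation_proportion(actmap: ActivationMap, band_index: int,
                                 window: tuple[float, float] = (1.0, 3.0)) -> np.ndarray:
    """Per-region fraction of trial x bin cells activated inside the window."""
    centers = 0.5 * (actmap.bin_edges[:-1] + actmap.bin_edges[1:])
    sel = (centers >= window[0] - 1e-12) & (centers <= window[1] + 1e-12)
    sub = actmap.state[:, :, band_index, :][:, :, sel]
    return (sub == 1).mean(axis=(0, 2))


def plot_region_map(values: np.ndarray, layout: ParcelLayout, title: str = "",
                    out: str | Path | None = None, vmax: float | None = None):
    """Scatter the per-region values on the schematic flat map."""
    xy = layout.coords()
    fig, ax = plt.subplots(figsize=(6, 3.2))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=120, cmap="inferno",
                    vmin=0, vmax=vmax, edgecolors="k", linewidths=0.3)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    if out is not None:
        fig.savefig(out, dpi=110)
        plt.close(fig)
    return fig


def render_activation_frames(spread_per_region: np.ndarray,
                             layout: ParcelLayout,
                             bin_edges: np.ndarray,
                             out_dir: str | Path,
                             band: str = "gamma",
                             vmax: float = 1.0) -> list[Path]:
    """One frame per 100 ms bin; marker color = trial-mean activation.

    spread_per_region: regions x bins array (e.g. per-region trial-mean
    activation indicator). Returns the written frame paths in time order.
    """
    spread_per_region = np.asarray(spread_per_region)
    if spread_per_region.size == 0:
        raise ValueError("empty activation input")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    xy = layout.coords()
    n_bins = spread_per_region.shape[1]
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    paths = []
    fig, ax = plt.subplots(figsize=(5, 2.8))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=spread_per_region[:, 0], s=100,
                    cmap="inferno", vmin=0, vmax=vmax, edgecolors="k",
                    linewidths=0.3)
    ax.set_aspect("equal")
    ax.set_axis_off()
    title = ax.set_title("")
    for k in range(n_bins):
        sc.set_array(spread_per_region[:, k])
        title.set_text(f"{band}  t = {centers[k]:+.2f} s")
        p = out_dir / f"frame_{k:04d}.png"
        fig.savefig(p, dpi=90)
        paths.append(p)
    plt.close(fig)
    return paths
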