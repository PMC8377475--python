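"""QC and summary figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .biomass import LagCurve
from .boundaries import RingWidths
from .profiles import GrayProfile
from .splines import SmoothFit

__all__ = ["qc_profile_plot", "calendar_plot", "lag_plot"]


def qc_profile_plot(profile: GrayProfile, widths: RingWidths, path,
                    fit: SmoothFit | None = None) -> None:
    """Profile + fitted spline + cambium/transition/boundary markers."""
    fig, ax = plt.subplots(figsize=(7, 4))
    pos, val = profile.finite()
    ax.plot(pos, val, ".", ms=2, color="0.6", label=f"{profile.kind} profile")
    if fit is not None:
        grid = np.linspace(fit.x_min, fit.x_max, 400)
        ax.plot(grid, fit.predict(grid), "r-", lw=1.5, label="spline fit")
    for x, color, label in ((widths.cambium_pos, "green", "cambium"),
                            (widths.transition_pos, "blue", "transition"),
                            (widths.prev_boundary_pos, "goldenrod", "prev. boundary")):
        ax.axvline(x, color=color, ls="--", label=label)
    ax.set_xlabel("radial position (μm, bark → pith)")
    ax.set_ylabel("mean gray value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def calendar_plot(phenology: pd.DataFrame, path) -> None:
    """Per-tree tb→te spans for size growth and mature-xylem production."""
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(phenology), 4) + 1.5))
    for i, (_, row) in enumerate(phenology.iterrows()):
        ax.plot([row["tb_incr"], row["te_incr"]], [i + 0.15] * 2, lw=4,
                color="seagreen")
        ax.plot([row["tb_mat"], row["te_mat"]], [i - 0.15] * 2, lw=4,
                color="saddlebrown")
        ax.text(row["tb_incr"], i + 0.28, f"{row['species']} t{row['tree']}",
                fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("day of year")
    ax.set_title("size growth (green) / mature-xylem production (brown)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def lag_plot(grid, width_completion, biomass_completion, lag: LagCurve, path) -> None:
    """Completion curves, rate curves with peak markers, and the lag trace."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    axes[0].plot(grid, width_completion, label="size growth", color="seagreen")
    axes[0].plot(grid, biomass_completion, label="biomass", color="saddlebrown")
    axes[0].set_ylabel("relative completion")
    axes[0].legend(fontsize=8)
    wr, br = np.diff(width_completion), np.diff(biomass_completion)
    axes[1].plot(grid[1:], wr, color="seagreen")
    axes[1].plot(grid[1:], br, color="saddlebrown")
    if wr.size and np.max(wr) > 0:
        axes[1].axvline(grid[1:][np.argmax(wr)], color="seagreen", ls=":")
    if br.size and np.max(br) > 0:
        axes[1].axvline(grid[1:][np.argmax(br)], color="saddlebrown", ls=":")
    axes[1].set_ylabel("daily rate (rel./day)")
    ok = np.isfinite(lag.lag)
    axes[2].plot(lag.doy_width[ok], lag.lag[ok], "k-")
    axes[2].set_ylabel("biomass − size lag (days)")
    axes[2].set_xlabel("day of year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
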