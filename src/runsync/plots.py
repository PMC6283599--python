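"""Diagnostic figures: circular resultant scatters and cadence-change curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["circular_resultant_scatter", "cadence_change_curves"]


def circular_resultant_scatter(per_song: pd.DataFrame, condition: str, ax=None):
    """Polar scatter of per-song resultant vectors for one condition.

    Each dot is one song of one participant: angle = mean relative phase,
    radius = resultant length (perimeter = perfect phase locking). The
    arrow shows the resultant of the whole distribution.
    """
    sub = per_song[(per_song["condition"] == condition) & (per_song["n_steps"] > 0)]
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.radians(sub["mean_phase_deg"].to_numpy(dtype=float))
    r = sub["resultant_length"].to_numpy(dtype=float)
    ax.scatter(theta, r, s=12, alpha=0.6)
    if theta.size:
        mean_c = np.mean(r * np.cos(theta))
        mean_s = np.mean(r * np.sin(theta))
        ax.annotate(
            "",
            xy=(np.arctan2(mean_s, mean_c), np.hypot(mean_c, mean_s)),
            xytext=(0.0, 0.0),
            arrowprops={"arrowstyle": "->", "color": "crimson", "lw": 2},
        )
    ax.set_ylim(0, 1)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_title(condition)
    return ax


def cadence_change_curves(per_song: pd.DataFrame, ax=None):
    """Mean per-song cadence change (vs silence) over songs, per condition."""
    if ax is None:
        _, ax = plt.subplots()
    grouped = per_song.groupby(["condition", "song"])["cadence_change_pct"]
    mean = grouped.mean().unstack("condition")
    sem = grouped.sem().unstack("condition")
    for condition in mean.columns:
        ax.errorbar(
            mean.index,
            mean[condition],
            yerr=sem[condition],
            marker="o",
            capsize=3,
            label=condition,
        )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("song")
    ax.set_ylabel("cadence change vs silence (%)")
    ax.legend(fontsize="small")
    return ax
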