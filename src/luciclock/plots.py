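"""Figure rendering: processed traces and Rayleigh (polar phase) plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .circular import rayleigh_critical_R

__all__ = ["plot_group_traces", "plot_rayleigh"]


def plot_group_traces(processed: pd.DataFrame, path: str | Path, release_h: float | None = None) -> None:
    """One panel per group: processed traces of all wells, overlaid.

    ``processed`` is a long table with columns time_h, well, group, value.
    """
    groups = [g for g in processed["group"].unique() if g != "blank"]
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(8, 2.2 * max(len(groups), 1)), sharex=True, squeeze=False
    )
    for ax, group in zip(axes[:, 0], groups):
        sub = processed[processed["group"] == group]
        for well, w in sub.groupby("well"):
            ax.plot(w["time_h"], w["value"], lw=0.6, alpha=0.6)
        if release_h is not None:
            ax.axvline(release_h, color="k", ls="--", lw=0.8)
        ax.set_ylabel("norm. lum.")
        ax.set_title(group, fontsize=9)
    axes[-1, 0].set_xlabel("hours of recording")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rayleigh(
    phases_h: np.ndarray,
    cycle_h: float,
    path: str | Path,
    *,
    mean_phase_h: float | None = None,
    resultant_R: float | None = None,
    alpha: float = 0.05,
    title: str = "",
) -> None:
    """Polar scatter of phases with the mean vector and the p = alpha circle."""
    phases_h = np.asarray(phases_h, dtype=float)
    theta = 2 * np.pi * phases_h / cycle_h
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.scatter(theta, np.full_like(theta, 1.05), s=18, zorder=3, clip_on=False)
    if len(phases_h) >= 2:
        crit = rayleigh_critical_R(len(phases_h), alpha)
        ax.plot(np.linspace(0, 2 * np.pi, 200), np.full(200, crit), color="gray", lw=0.8)
    if mean_phase_h is not None and resultant_R is not None:
        mt = 2 * np.pi * mean_phase_h / cycle_h
        ax.annotate(
            "",
            xy=(mt, resultant_R),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="-|>", color="crimson", lw=1.5),
        )
    ax.set_rlim(0, 1.1)
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    ax.set_xticklabels([f"{cycle_h * k / 8:g}" for k in range(8)])
    ax.set_yticklabels([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
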