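"""Minimal summary plots for session results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_occupancy_timecourse(metrics: pd.DataFrame, ax=None):
    """Perch-1 occupancy and landing rate over days, one line per bird."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for bird, sub in metrics.groupby("bird_id"):
        sub = sub.sort_values("day")
        ax.plot(sub["day"], sub["perch1_occupancy"], "o-", alpha=0.6, label=f"bird {bird}")
    ax.axhline(0.5, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel("perch 1 occupancy")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_pitch_timecourse(renditions: pd.DataFrame, ax=None):
    """Daily mean measured pitch per bird, baseline and contingency phases."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for bird, sub in renditions.groupby("bird_id"):
        daily = sub.groupby("day")["pitch_hz"].mean()
        ax.plot(daily.index, daily.values, "o-", alpha=0.6, label=f"bird {bird}")
    ax.set_xlabel("day")
    ax.set_ylabel("mean pitch (Hz)")
    return ax
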