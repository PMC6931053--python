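"""Plots of cohort consistency-rate trends."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_group_consistency"]


def plot_group_consistency(mean_series: pd.Series, target: str = "steps", ax=None):
    """Line plot of the group-mean consistency rate versus program day.

    The series starts on the first day with a complete trailing window
    (day 7 for a weekly window).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(mean_series.index, mean_series.to_numpy(), marker="o", ms=3, lw=1.2)
    ax.set_ylim(0, 1)
    ax.set_ylabel("consistency rate")
    ax.set_xlabel("day")
    ax.set_title(f"Group mean consistency rate ({target} target, 7-day window)")
    ax.grid(alpha=0.3)
    return ax
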