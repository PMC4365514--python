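"""Seasonal boxplot and repeatability summaries.

Figure-style views of the long trait table: per-campaign boxplots of
genotype means over thermal time, and repeatability (h2) against thermal
time for each plot size.  All functions return the matplotlib figure; the
caller decides whether to save or show it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_seasonal_boxplots", "plot_repeatability"]


def plot_seasonal_boxplots(
    table: pd.DataFrame, trait: str, rows_per_plot: int = 4, ax=None
):
    """Boxplots of per-genotype means of one trait against thermal time.

    Each box summarises the 16 genotype means (averaged over blocks) of the
    given plot size at one campaign, the convention used for seasonal trait
    summaries.
    """
    sub = table[(table["trait"] == trait)
                & (table["rows_per_plot"] == rows_per_plot)]
    means = (
        sub.groupby(["degree_days", "genotype"])["value"].mean().reset_index()
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups = [g["value"].to_numpy() for _, g in means.groupby("degree_days")]
    positions = sorted(means["degree_days"].unique())
    ax.boxplot(groups, positions=positions, widths=25, showmeans=True,
               meanline=True)
    ax.set_xlabel("thermal time (degC days)")
    ax.set_ylabel(trait)
    ax.set_title(f"{trait}, {rows_per_plot}-row plots (16 genotype means)")
    return ax.figure


def plot_repeatability(profile: pd.DataFrame, trait: str = "", ax=None):
    """Repeatability against thermal time, one line per plot size."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x_col = "degree_days" if "degree_days" in profile.columns else "campaign"
    for rpp, grp in profile.groupby("rows_per_plot"):
        grp = grp.sort_values(x_col)
        ax.plot(grp[x_col], grp["h2"], marker="o", label=f"{rpp} row(s)")
    ax.set_xlabel("thermal time (degC days)" if x_col == "degree_days"
                  else "campaign")
    ax.set_ylabel("repeatability $h^2$")
    ax.set_ylim(0, 1.05)
    ax.legend(title="plot size")
    if trait:
        ax.set_title(f"repeatability of {trait} by plot size")
    return ax.figure
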