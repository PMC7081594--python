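"""Publication-style plots: grouped bars with plate points, and correlation
scatters with a 95% confidence band. Styling is utilitarian, not a
compatibility surface."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .stats import RegressionFit

__all__ = ["bar_rates_plot", "correlation_plot", "reu_bars_plot"]


def bar_rates_plot(
    summary: pd.DataFrame,
    plates: pd.DataFrame,
    group_key: str,
    value: str = "rate",
    path: str | Path | None = None,
    ylabel: str = "radial extension rate (mm/day)",
    loq: float | None = 2.0,
) -> Figure:
    """Bar = group mean, error bar = SD across plates, points = plates."""
    fig = Figure(figsize=(1.2 + 0.9 * len(summary), 3.2))
    ax = fig.add_subplot(111)
    labels = summary[group_key].astype(str).tolist()
    x = np.arange(len(labels))
    mean_col = "mean_rate" if "mean_rate" in summary else f"mean_{value}"
    sd_col = "sd_rate" if "sd_rate" in summary else f"sd_{value}"
    ax.bar(x, summary[mean_col], yerr=summary[sd_col].fillna(0), capsize=3,
           color="#9ecae1", edgecolor="k", linewidth=0.6)
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, lbl in enumerate(labels):
        pts = plates.loc[plates[group_key].astype(str) == lbl, value]
        ax.plot(i + rng.uniform(-0.15, 0.15, len(pts)), pts, "o", ms=3.5,
                color="#08306b", alpha=0.75, zorder=3)
    if loq is not None:
        ax.axhline(loq, ls="--", lw=0.8, color="gray")
    ax.set_xticks(x, labels, rotation=30, ha="right")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def correlation_plot(
    fit: RegressionFit,
    path: str | Path | None = None,
    xlabel: str = "mean rate, x condition (mm/day)",
    ylabel: str = "mean rate, y condition (mm/day)",
) -> Figure:
    """Paired group means with x/y error bars, OLS line and 95% CI band."""
    fig = Figure(figsize=(4, 3.6))
    ax = fig.add_subplot(111)
    ax.errorbar(fit.x, fit.y, xerr=fit.x_sd, yerr=fit.y_sd, fmt="o", ms=4,
                color="#08306b", ecolor="gray", elinewidth=0.8, capsize=2)
    ax.fill_between(fit.band_x, fit.band_lower, fit.band_upper,
                    color="k", alpha=0.15, lw=0)
    ax.plot(fit.band_x, fit.predict(fit.band_x), "k-", lw=1.2)
    ax.annotate(f"$R^2$ = {fit.r_squared:.2f}", xy=(0.05, 0.92),
                xycoords="axes fraction")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def reu_bars_plot(
    reu_table: pd.DataFrame,
    path: str | Path | None = None,
    group_key: str = "organism",
) -> Figure:
    """Per-group mean REU across labs with individual plate points."""
    grp = reu_table.groupby(group_key)["reu"]
    summary = pd.DataFrame(
        {group_key: grp.mean().index, "mean_reu": grp.mean().values,
         "sd_reu": grp.std(ddof=1).values}
    )
    fig = Figure(figsize=(1.2 + 0.9 * len(summary), 3.2))
    ax = fig.add_subplot(111)
    x = np.arange(len(summary))
    ax.bar(x, summary["mean_reu"], yerr=np.nan_to_num(summary["sd_reu"]),
           capsize=3, color="#a1d99b", edgecolor="k", linewidth=0.6)
    rng = np.random.default_rng(0)
    for i, lbl in enumerate(summary[group_key]):
        pts = reu_table.loc[reu_table[group_key] == lbl, "reu"]
        ax.plot(i + rng.uniform(-0.15, 0.15, len(pts)), pts, "o", ms=3.5,
                color="#00441b", alpha=0.75, zorder=3)
    ax.axhline(1.0, ls="--", lw=0.8, color="gray")
    ax.set_xticks(x, summary[group_key].astype(str), rotation=30, ha="right")
    ax.set_ylabel("relative extension units (REU)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
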