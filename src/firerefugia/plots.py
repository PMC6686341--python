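"""Diagnostic figures: per-lek trend panels, category boxplots, and the
averaged-coefficient dot-and-CI chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trends import LekSurveySeries, TrendFit

__all__ = ["plot_lek_trend", "plot_category_boxplots", "plot_averaged_coefficients"]


def plot_lek_trend(series: LekSurveySeries, fit: TrendFit, ax=None):
    """Observed counts with the fitted pre- and postfire segments."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(series.years, series.males, s=18, color="k", zorder=3, label="observed")
    pre = series.years < series.fire_year
    post = ~pre
    b0, b1, b2, b3 = fit.beta
    x1 = series.years - series.fire_year
    if pre.any():
        ax.plot(series.years[pre], np.exp(b0 + b1 * x1[pre]), color="tab:blue", label="prefire fit")
    if post.any() and not fit.post_unbounded:
        ax.plot(series.years[post], np.exp(b0 + b2 + (b1 + b3) * x1[post]),
                color="tab:red", label="postfire fit")
    ax.axvline(series.fire_year, color="gray", ls="--", lw=1)
    ax.set_xlabel("year")
    ax.set_ylabel("peak male count")
    ax.set_title(series.lek_id)
    ax.legend(fontsize=8)
    return ax


def plot_category_boxplots(comparisons: pd.DataFrame, trend_table: pd.DataFrame, path: str | Path):
    """Per-category boxplots of pre- vs postfire slopes with test results."""
    cats = list(comparisons["category"])
    fig, axes = plt.subplots(1, max(len(cats), 1), figsize=(3 * max(len(cats), 1), 3.5),
                             squeeze=False)
    for ax, cat in zip(axes[0], cats):
        sub = trend_table[trend_table["category"] == cat]
        ax.boxplot([sub["pre_slope"], sub["post_slope"]], tick_labels=["pre", "post"])
        row = comparisons[comparisons["category"] == cat].iloc[0]
        ax.set_title(f"{cat}\n{row['test']}: stat={row['statistic']:.2f}, p={row['p_value']:.2g}",
                     fontsize=9)
        ax.axhline(0, color="gray", lw=0.8)
        ax.set_ylabel("trend (log males / yr)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_averaged_coefficients(averaged: pd.DataFrame, path: str | Path):
    """Dot-and-CI chart; CIs excluding zero are drawn in black, others gray."""
    df = averaged.iloc[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(df) + 1.5))
    ypos = np.arange(len(df))
    sig = (df["lower"] > 0) | (df["upper"] < 0)
    for i, (_, r) in enumerate(df.iterrows()):
        color = "black" if sig.iloc[i] else "gray"
        ax.errorbar(r["estimate"], i, xerr=[[r["estimate"] - r["lower"]], [r["upper"] - r["estimate"]]],
                    fmt="o", color=color, capsize=3)
    ax.axvline(0, color="gray", ls="--", lw=0.8)
    ax.set_yticks(ypos, df["predictor"] if "predictor" in df else df.index)
    ax.set_xlabel("standardized averaged coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
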