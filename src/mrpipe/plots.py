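"""Matplotlib rendering of the diagnostic plot data.

All functions take the plot-ready tables from :mod:`mrpipe.diagnostics` and
return a Figure; writing image files is the CLI's job. Uses the Agg backend
implicitly (no display required).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_figure(forest: pd.DataFrame, title: str = "") -> plt.Figure:
    """Forest plot of per-SNP odds ratios plus the pooled row."""
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(forest) + 1.5))
    y = np.arange(len(forest))[::-1]
    ax.errorbar(
        forest["OR"], y,
        xerr=[forest["OR"] - forest["CI_LOW"], forest["CI_HIGH"] - forest["OR"]],
        fmt="s", color="black", ecolor="gray", capsize=2, markersize=4,
    )
    ax.axvline(1.0, color="red", linestyle=":", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(forest["SNP"])
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def scatter_figure(
    points: pd.DataFrame, lines: pd.DataFrame, title: str = ""
) -> plt.Figure:
    """SNP effect scatter with one fitted line per method."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        points["BETA_EXP"], points["BETA_OUT"],
        xerr=points["SE_EXP"], yerr=points["SE_OUT"],
        fmt="o", color="black", ecolor="lightgray", markersize=3,
    )
    xs = np.linspace(0, points["BETA_EXP"].max() * 1.05, 50)
    for row in lines.itertuples(index=False):
        ax.plot(xs, row.INTERCEPT + row.SLOPE * xs, label=row.METHOD)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def leave_one_out_figure(loo: pd.DataFrame, title: str = "") -> plt.Figure:
    """Forest-style plot of IVW estimates, each excluding one SNP."""
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(loo) + 1.5))
    y = np.arange(len(loo))[::-1]
    ax.errorbar(
        loo["OR"], y,
        xerr=[loo["OR"] - loo["CI_LOW"], loo["CI_HIGH"] - loo["OR"]],
        fmt="s", color="black", ecolor="gray", capsize=2, markersize=4,
    )
    ax.axvline(1.0, color="red", linestyle=":", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(loo["EXCLUDED"])
    ax.set_xscale("log")
    ax.set_xlabel("IVW odds ratio excluding each SNP")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def funnel_figure(funnel: pd.DataFrame, title: str = "") -> plt.Figure:
    """Funnel plot: per-SNP ratio against its precision."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(funnel["BETA"], funnel["PRECISION"], s=12, color="black")
    ax.set_xlabel("Per-SNP causal estimate")
    ax.set_ylabel("Precision (1/SE)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
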