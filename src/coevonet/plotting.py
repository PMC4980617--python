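"""Minimal figure panels for simulation output.

Layout fidelity to any particular publication style is a non-goal; these
helpers give quick visual checks of an ensemble or variant comparison.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_prevalence(series_by_variant: dict[str, pd.DataFrame], ax=None):
    """Smoking prevalence over time, one line per variant."""
    ax = ax or plt.gca()
    for variant, series in series_by_variant.items():
        ax.plot(series["step"], series["prevalence"], label=variant)
    ax.set_xlabel("time step")
    ax.set_ylabel("prevalence S/N")
    ax.legend(fontsize="small")
    return ax


def plot_evc(series: pd.DataFrame, onset_step: int, ax=None):
    """Mean eigenvector centrality of smokers vs non-smokers, normalised to
    the forcing-onset baseline."""
    ax = ax or plt.gca()
    for col, label in [("evc_smokers", "smokers"), ("evc_nonsmokers", "non-smokers")]:
        base = series.loc[series["step"] == onset_step, col]
        base = float(base.iloc[0]) if len(base) else np.nan
        ax.plot(series["step"], series[col] / base, label=label)
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("time step")
    ax.set_ylabel("mean EVC (normalised)")
    ax.legend(fontsize="small")
    return ax


def plot_cp(series: pd.DataFrame, onset_step: int, max_distance: int = 5, ax=None):
    """Conditional smoking probability by social distance, as percentage
    change relative to the forcing-onset value."""
    ax = ax or plt.gca()
    for d in range(1, max_distance + 1):
        col = f"cp_d{d}"
        if col not in series:
            continue
        base = series.loc[series["step"] == onset_step, col]
        base = float(base.iloc[0]) if len(base) else np.nan
        ax.plot(series["step"], 100.0 * (series[col] - base) / base, label=f"d={d}")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("time step")
    ax.set_ylabel("CP change (%)")
    ax.legend(fontsize="small")
    return ax


def panel_figure(series_by_variant: dict[str, pd.DataFrame], onset_step: int, path=None):
    """One page: prevalence per variant, plus EVC and CP panels for each."""
    n = len(series_by_variant)
    fig, axes = plt.subplots(1 + n, 2, figsize=(9, 3 * (1 + n)))
    plot_prevalence(series_by_variant, ax=axes[0, 0])
    axes[0, 1].axis("off")
    for row, (variant, series) in enumerate(series_by_variant.items(), start=1):
        if "evc_smokers" in series:
            plot_evc(series, onset_step, ax=axes[row, 0])
            axes[row, 0].set_title(variant, fontsize="small")
        if any(c.startswith("cp_d") for c in series.columns):
            plot_cp(series, onset_step, ax=axes[row, 1])
            axes[row, 1].set_title(variant, fontsize="small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
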