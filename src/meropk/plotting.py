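"""Diagnostic figures: PE box plots, pcVPC bands, NPDE histogram/QQ, EBE
densities and predicted-trough box plots with the therapeutic window."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy import stats  # noqa: E402

from .dosing import TARGET_HIGH, TARGET_LOW  # noqa: E402

__all__ = [
    "plot_pe_boxplots",
    "plot_vpc",
    "plot_npde",
    "plot_ebe",
    "plot_trough_boxes",
]


def plot_pe_boxplots(pe_by_model: dict, ax=None):
    """Box plots of PE% per model with 0 / ±30% reference lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(len(pe_by_model), 4), 4))
    labels = list(pe_by_model)
    ax.boxplot([pe_by_model[m] for m in labels], tick_labels=labels,
               showfliers=True)
    ax.axhline(0.0, ls="--", c="k", lw=0.8)
    for y in (-30.0, 30.0):
        ax.axhline(y, ls=":", c="k", lw=0.8)
    ax.set_ylabel("PE (%)")
    ax.tick_params(axis="x", rotation=60)
    return ax.figure


def plot_vpc(vpc_result, ax=None, log_y: bool = True):
    """Observed percentiles over the simulated 90% confidence bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = vpc_result.table
    for q, color in ((5, "tab:blue"), (50, "tab:red"), (95, "tab:blue")):
        sub = t[t.percentile == q].sort_values("t_mid")
        ax.fill_between(sub.t_mid, sub.band_lo, sub.band_hi, alpha=0.25,
                        color=color, lw=0)
        ax.plot(sub.t_mid, sub.observed, "o-", color=color, ms=4,
                label=f"observed p{q}")
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.legend(fontsize=8)
    return ax.figure


def plot_npde(npde_result, axes=None):
    """NPDE histogram with the N(0,1) density, and a normal QQ plot."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 4))
    x = npde_result.npde
    axes[0].hist(x, bins="auto", density=True, alpha=0.7)
    grid = np.linspace(-4, 4, 200)
    axes[0].plot(grid, stats.norm.pdf(grid), "k-", lw=1)
    axes[0].set_xlabel("NPDE")
    stats.probplot(x, dist="norm", plot=axes[1])
    axes[1].set_title("")
    return axes[0].figure


def plot_ebe(ebe_result, parameter: str = "cl", ax=None):
    """Estimated EBE histogram vs the theoretical N(0, ω²) density, with
    20th/80th percentiles of both."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    d = ebe_result.parameters[parameter]
    sample, w = d["sample"], d["omega_sd"]
    ax.hist(sample, bins="auto", density=True, alpha=0.6, label="estimated")
    grid = np.linspace(-4 * w, 4 * w, 200)
    ax.plot(grid, stats.norm.pdf(grid, scale=w), c="purple", label="theoretical")
    for x, c in ((d["est_p20"], "tab:blue"), (d["est_p80"], "tab:blue"),
                 (d["theo_p20"], "purple"), (d["theo_p80"], "purple")):
        ax.axvline(x, ls="--", c=c, lw=0.8)
    ax.set_xlabel(f"eta_{parameter} ({ebe_result.model_id})")
    ax.legend(fontsize=8)
    return ax.figure


def plot_trough_boxes(trough_by_method: dict, ax=None):
    """Predicted troughs per method with the 8–45 mg/L window shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = list(trough_by_method)
    ax.boxplot([trough_by_method[m] for m in labels], tick_labels=labels)
    ax.axhspan(TARGET_LOW, TARGET_HIGH, color="0.9")
    for y in (TARGET_LOW, TARGET_HIGH):
        ax.axhline(y, ls=":", c="k", lw=0.8)
    ax.set_ylabel("trough concentration (mg/L)")
    return ax.figure
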