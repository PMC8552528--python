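"""Basic plots: trajectory panels, trimester bars, RM-ASCA+ score/loading
panels, Fine-Gray forest plots and VIP bars.  Figures only; all numbers come
from the analysis modules."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def trajectory_panel(fits, ncols: int = 4, figsize=None):
    """Grid of fitted trajectories with pointwise bands."""
    n = len(fits)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=figsize or (3 * ncols, 2.2 * nrows),
                             squeeze=False)
    for ax, fit in zip(axes.flat, fits):
        ax.plot(fit.grid, fit.mean_curve, color="tab:blue")
        ax.fill_between(fit.grid, fit.band[0], fit.band[1], alpha=0.25,
                        color="tab:blue", lw=0)
        ax.set_title(fit.cytokine, fontsize=9)
        ax.set_xlabel("GA (days)", fontsize=7)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    return fig


def sca_panel(model, partition: str = "time"):
    """Score trajectories (left) and loadings (right) for one partition."""
    scores = model.scores_[partition]
    loadings = model.loadings_[partition]
    ncomp = scores.shape[1]
    fig, axes = plt.subplots(ncomp, 2, figsize=(9, 2.6 * ncomp), squeeze=False)
    bands = getattr(model, "bands_", {}).get(partition)
    x = np.arange(len(scores))
    for i, comp in enumerate(scores.columns):
        ax = axes[i, 0]
        ax.plot(x, scores[comp], marker="o")
        if bands:
            ax.vlines(x, bands["scores_lo"][comp], bands["scores_hi"][comp],
                      color="gray", lw=1)
        ax.set_xticks(x, ["/".join(str(v) for v in t if v is not None)
                          if isinstance(t, tuple) else str(t) for t in scores.index],
                      rotation=45, fontsize=7)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(f"{partition} {comp} scores", fontsize=9)
        ax = axes[i, 1]
        order = loadings[comp].sort_values().index
        y = np.arange(len(order))
        ax.barh(y, loadings.loc[order, comp])
        if bands:
            ax.hlines(y, bands["loadings_lo"].loc[order, comp],
                      bands["loadings_hi"].loc[order, comp], color="gray", lw=1)
        ax.set_yticks(y, order, fontsize=6)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(f"{comp} loadings", fontsize=9)
    fig.tight_layout()
    return fig


def finegray_forest(fg_table):
    """Hazard-ratio forest plot, one row per analyte."""
    df = fg_table.dropna(subset=["beta"]).sort_values("beta")
    y = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(5, 0.28 * len(df) + 1.2))
    ax.errorbar(df["hr"], y, xerr=[df["hr"] - np.exp(df["beta"] - 1.96 * df["se"]),
                                   np.exp(df["beta"] + 1.96 * df["se"]) - df["hr"]],
                fmt="o", color="tab:blue", ecolor="gray", capsize=2)
    ax.axvline(1.0, color="k", lw=0.6)
    ax.set_yticks(y, df["cytokine"], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("subdistribution hazard ratio (per SD log conc.)")
    fig.tight_layout()
    return fig


def vip_plot(vip: dict):
    """VIP bar plot; the conventional importance cut at 1 is drawn."""
    items = sorted(vip.items(), key=lambda kv: kv[1], reverse=True)
    names, vals = zip(*items)
    fig, ax = plt.subplots(figsize=(0.35 * len(names) + 1.5, 3))
    ax.bar(np.arange(len(names)), vals)
    ax.axhline(1.0, color="red", lw=0.8, ls="--")
    ax.set_xticks(np.arange(len(names)), names, rotation=90, fontsize=7)
    ax.set_ylabel("VIP")
    fig.tight_layout()
    return fig
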