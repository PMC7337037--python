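"""Optional matplotlib figures for the two paradigms."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_traditional", "plot_illustration"]

_COND_COLORS = {"none": "0.4", "negative": "tab:blue",
                "normal": "tab:green", "positive": "tab:red"}


def plot_traditional(tidy: pd.DataFrame, path: str | Path) -> Path:
    """Explained variance vs subgroup mean ability, one panel per loading."""
    loadings = sorted(tidy["selection_loading"].unique())
    fig, axes = plt.subplots(1, len(loadings), figsize=(4.2 * len(loadings), 3.6),
                             sharey=True, squeeze=False)
    for ax, loading in zip(axes[0], loadings):
        sub = tidy[tidy["selection_loading"] == loading]
        for cond, grp in sub.groupby("condition"):
            for _, rep in grp.groupby("replicate"):
                rep = rep.sort_values("subgroup_mean_sv")
                ax.plot(rep["subgroup_mean_sv"], rep["explained_variance"],
                        color=_COND_COLORS.get(cond, "k"), alpha=0.35, lw=0.8)
        ax.set_title(f"selection loading = {loading}")
        ax.set_xlabel("subgroup mean (selection variable)")
    axes[0][0].set_ylabel("first-PC explained variance")
    handles = [plt.Line2D([], [], color=c, label=l) for l, c in _COND_COLORS.items()]
    axes[0][-1].legend(handles=handles, fontsize=8, title="disturbance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_illustration(report: dict, path: str | Path) -> Path:
    """Four-panel single-run illustration (true g, estimated g, test vs g)."""
    pop = report["_population"]
    g_hat = report["_g_hat"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    axes[0, 0].hist(pop.true_g, bins=60, color="0.6")
    axes[0, 0].set_title(f"true g (skew {report['true_g_skew']:.3f})")
    axes[0, 1].hist(g_hat, bins=60, color="tab:blue")
    axes[0, 1].set_title(f"estimated g (skew {report['estimated_g_skew']:.3f})")
    axes[1, 0].scatter(pop.true_g, pop.true_scores[:, 0], s=2, alpha=0.2)
    axes[1, 0].set_xlabel("true g")
    axes[1, 0].set_ylabel("true score, test 1")
    ax = axes[1, 1]
    ax.scatter(g_hat, pop.observed_scores[:, 0], s=2, alpha=0.2)
    order = np.argsort(g_hat)
    lin = np.polynomial.polynomial.polyfit(g_hat, pop.observed_scores[:, 0], 1)
    quad = np.polynomial.polynomial.polyfit(g_hat, pop.observed_scores[:, 0], 2)
    ax.plot(g_hat[order], np.polynomial.polynomial.polyval(g_hat[order], lin),
            "k-", lw=1.5)
    ax.plot(g_hat[order], np.polynomial.polynomial.polyval(g_hat[order], quad),
            "r-", lw=1.5)
    ax.set_xlabel("estimated g")
    ax.set_ylabel("observed score, test 1")
    ax.set_title(f"quadratic B = {report['quadratic_B']:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
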