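"""Publication-style figures for pipeline outputs (written as PNG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trajectories", "plot_roc", "plot_dendrogram"]

_PHENO_COLORS = {"MD": "tab:blue", "FD": "tab:red"}


def plot_trajectories(trajectories, phenotypes, path: str | Path) -> None:
    """Spaghetti plot of cognitive trajectories colored by phenotype."""
    fig, ax = plt.subplots(figsize=(5, 4))
    months = trajectories.visit_months
    for row, ph in zip(trajectories.scores, phenotypes):
        ax.plot(months, row, color=_PHENO_COLORS.get(str(ph), "gray"), alpha=0.25, lw=0.8)
    for ph, color in _PHENO_COLORS.items():
        mask = np.asarray(phenotypes) == ph
        if mask.any():
            ax.plot(months, trajectories.scores[mask].mean(axis=0), color=color, lw=2.5,
                    label=f"{ph} (n={int(mask.sum())})")
    ax.set_xlabel("months from baseline")
    ax.set_ylabel("cognitive score")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(results, path: str | Path) -> None:
    """ROC panel for a list of AblationResult objects."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for res in results:
        ax.plot(res.roc[:, 0], res.roc[:, 1], lw=1.5,
                label=f"{res.combination} (AUC={res.pooled_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(merge_tree, n: int, path: str | Path) -> None:
    """Dendrogram from a merge tree (scipy rendering)."""
    from scipy.cluster.hierarchy import dendrogram

    Z = np.array([[rec.a, rec.b, max(rec.height, 1e-12), rec.size] for rec in merge_tree])
    # enforce monotone heights for rendering only
    Z[:, 2] = np.maximum.accumulate(Z[:, 2])
    fig, ax = plt.subplots(figsize=(6, 4))
    dendrogram(Z, ax=ax, no_labels=True, color_threshold=0)
    ax.set_ylabel("merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
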