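"""Figure exports: dendrogram, selection curves, territorial map, PC plane,
morphotype distribution bars.  Content is reproducible; byte-identity of
the image files is not guaranteed."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

__all__ = [
    "plot_dendrogram",
    "plot_selection_curves",
    "plot_territorial_map",
    "plot_pc_plane",
    "plot_distribution",
]


def _finish(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(linkage_tree: np.ndarray, path: str | Path, cut_k: int | None = None):
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(linkage_tree, ax=ax, no_labels=True, color_threshold=None)
    if cut_k is not None and cut_k >= 2:
        n = len(linkage_tree) + 1
        height = (linkage_tree[n - cut_k, 2] + linkage_tree[n - cut_k - 1, 2]) / 2
        ax.axhline(height, ls="--", c="k", lw=0.8)
    ax.set_xlabel("cells")
    ax.set_ylabel("linkage distance")
    _finish(fig, path)


def plot_selection_curves(thorndike, vrc, path: str | Path):
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    ax1.plot(thorndike.ks, thorndike.curve, "o-")
    ax1.axvline(thorndike.chosen_k, ls="--", c="k", lw=0.8)
    ax1.set_xlabel("number of clusters")
    ax1.set_ylabel("mean within-cluster distance")
    ax2.plot(vrc.ks, vrc.curve, "o-")
    ax2.axvline(vrc.chosen_k, ls="--", c="k", lw=0.8)
    ax2.set_xlabel("number of clusters")
    ax2.set_ylabel("variance ratio criterion")
    _finish(fig, path)


def plot_territorial_map(scores: pd.DataFrame, centroids: pd.DataFrame, path: str | Path):
    """Cells on the (LD1, LD2) plane colored by the 'label' column."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for lab, grp in scores.groupby("label"):
        ax.scatter(grp.iloc[:, 0], grp.iloc[:, 1], s=12, alpha=0.7, label=str(lab))
    ax.scatter(
        centroids.iloc[:, 0], centroids.iloc[:, 1],
        marker="X", s=120, c="black", label="centroids",
    )
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1])
    ax.legend(fontsize=8)
    _finish(fig, path)


def plot_pc_plane(scores: pd.DataFrame, labels, path: str | Path, explained=None):
    fig, ax = plt.subplots(figsize=(5, 5))
    labels = pd.Series(np.asarray(labels), index=scores.index)
    for lab, idx in labels.groupby(labels).groups.items():
        ax.scatter(scores.loc[idx, "PC1"], scores.loc[idx, "PC2"], s=12, alpha=0.7,
                   label=str(lab))
    sx = f"PC1 ({explained[0] * 100:.1f}%)" if explained is not None else "PC1"
    sy = f"PC2 ({explained[1] * 100:.1f}%)" if explained is not None else "PC2"
    ax.set_xlabel(sx)
    ax.set_ylabel(sy)
    ax.legend(fontsize=8)
    _finish(fig, path)


def plot_distribution(report: pd.DataFrame, path: str | Path, level: str = "cluster"):
    """Stacked percentage bars per stratum."""
    strata_cols = [c for c in report.columns if c not in (level, "n", "percent")]
    pivot = report.pivot_table(
        index=strata_cols, columns=level, values="percent", fill_value=0.0, observed=True
    )
    ax = pivot.plot(kind="bar", stacked=True, figsize=(8, 4))
    ax.set_ylabel("% of cells")
    _finish(ax.figure, path)
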