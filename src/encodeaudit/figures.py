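"""Figure generation for audit reports (matplotlib, non-interactive)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .inspection import InspectionResult

__all__ = ["plot_split_panel", "plot_inspection"]


def plot_split_panel(panel: pd.DataFrame, out_path: str | Path) -> None:
    """Bar chart of per-class one-vs-rest AUC over panel backbones."""
    fig, ax = plt.subplots(figsize=(8, 3.2))
    order = panel["backbone_id"].unique().tolist()
    classes = panel["class"].unique().tolist()
    width = 0.8 / max(len(classes), 1)
    for j, cls in enumerate(classes):
        sub = panel[panel["class"] == cls].set_index("backbone_id").reindex(order)
        xs = [i + j * width for i in range(len(order))]
        err = None
        if {"auc_lo", "auc_hi"} <= set(sub.columns):
            err = [sub["auc"] - sub["auc_lo"], sub["auc_hi"] - sub["auc"]]
        ax.bar(xs, sub["auc"], width=width, label=str(cls), yerr=err, capsize=2)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(order))])
    ax.set_xticklabels(order, rotation=20, ha="right", fontsize=7)
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_ylabel("one-vs-rest AUC")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_inspection(result: InspectionResult, out_path: str | Path) -> None:
    """PCA mode pairs, t-SNE, and paired-logit scatters with group overlay."""
    idx = result.plot_indices
    overlay = result.overlay.iloc[idx].reset_index(drop=True)
    fig, axes = plt.subplots(1, 4, figsize=(13, 3))
    panels = [
        (result.pca_projections[idx, 0], result.pca_projections[idx, 1], "PCA 1", "PCA 2"),
        (result.pca_projections[idx, 2], result.pca_projections[idx, 3], "PCA 3", "PCA 4"),
        (result.tsne_xy[idx, 0], result.tsne_xy[idx, 1], "t-SNE 1", "t-SNE 2"),
        (result.logit_xy[idx, 0], result.logit_xy[idx, 1],
         "logit no_finding", "logit condition_x"),
    ]
    for ax, (x, y, xl, yl) in zip(axes, panels):
        for g in sorted(overlay["group"].unique()):
            mask = (overlay["group"] == g).to_numpy()
            ax.scatter(x[mask], y[mask], s=3, alpha=0.4, label=str(g))
        ax.set_xlabel(xl, fontsize=8)
        ax.set_ylabel(yl, fontsize=8)
        ax.tick_params(labelsize=7)
    axes[0].legend(fontsize=7, markerscale=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
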