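"""Figures: PC1 box plots by group and the pull-down abundance heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_pc1_boxplot", "plot_pulldown_heatmap"]

_MARKERS = ("o", "s", "^", "D", "v", "P")


def plot_pc1_boxplot(pc1, labels, path, *, timepoints=None, title="PC1 by group"):
    """Box plot of per-sample PC1 scores split by condition group; sample
    symbols optionally coded by timepoint."""
    pc1 = pd.Series(pc1)
    labels = pd.Series(labels, index=pc1.index)
    groups = list(pd.unique(labels))
    data = [pc1[labels == g].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.5 * len(groups) + 2, 4))
    ax.boxplot(data, tick_labels=groups, showfliers=False)
    rng = np.random.default_rng(0)
    for gi, g in enumerate(groups, start=1):
        vals = pc1[labels == g]
        x = gi + rng.uniform(-0.12, 0.12, size=len(vals))
        if timepoints is not None:
            tp = pd.Series(timepoints, index=pc1.index)[vals.index]
            for mi, t in enumerate(pd.unique(tp)):
                sel = tp == t
                ax.scatter(x[sel.to_numpy()], vals[sel], s=14, alpha=0.7,
                           marker=_MARKERS[mi % len(_MARKERS)], label=t if gi == 1 else None)
        else:
            ax.scatter(x, vals, s=14, alpha=0.7)
    if timepoints is not None:
        ax.legend(title="timepoint", fontsize=7)
    ax.set_ylabel("PC1 score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pulldown_heatmap(L: pd.DataFrame, path, *, groups=None, title="log2 relative abundance"):
    """Heatmap of the log2 relative-abundance matrix; grey = not detected."""
    fig, ax = plt.subplots(
        figsize=(0.45 * L.shape[1] + 3, 0.28 * L.shape[0] + 2)
    )
    masked = np.ma.masked_invalid(L.to_numpy(dtype=float))
    cmap = plt.get_cmap("Reds").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, aspect="auto", cmap=cmap)
    ax.set_xticks(range(L.shape[1]))
    cols = [f"{c}\n[{groups[c]}]" if groups else str(c) for c in L.columns]
    ax.set_xticklabels(cols, rotation=90, fontsize=7)
    ax.set_yticks(range(L.shape[0]))
    ax.set_yticklabels(L.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.7, label="log2 rel. abundance")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
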