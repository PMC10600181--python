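"""Figure helpers: PCA scatter colored by batch, diagnostic boxplots."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import PcaScores, KbetResult, SilhouetteResult

__all__ = ["pca_scatter", "diagnostics_boxplots"]


def pca_scatter(pc: PcaScores, batch: np.ndarray, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for lab in np.unique(batch):
        m = batch == lab
        ax.scatter(pc.scores[m, 0], pc.scores[m, 1], s=12, alpha=0.7,
                   label=f"batch {lab}")
    ev = pc.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    if pc.scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def diagnostics_boxplots(kbet_results: dict[str, KbetResult],
                         sil_results: dict[str, SilhouetteResult],
                         path) -> None:
    """Side-by-side boxplots of kBET rejection indicators and silhouettes."""
    names = list(kbet_results)
    fig, axes = plt.subplots(1, 2, figsize=(2 + 1.4 * len(names), 4))
    axes[0].boxplot([kbet_results[n].rejected for n in names], labels=names)
    axes[0].set_ylabel("kBET rejection indicator")
    axes[1].boxplot([sil_results[n].s for n in names], labels=names)
    axes[1].set_ylabel("silhouette $s_i$")
    for ax in axes:
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
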