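"""Figures: per-sample ρ box plots, PLS-DA score and loading plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .tissue import CLASS_NAMES


def rho_boxplot(predictions: pd.DataFrame, path: str,
                by: str = "tissue_class") -> None:
    """Box plot of per-plane mean pathologic probability ρ, grouped by
    tissue class (or ROI/sample via ``by``)."""
    groups = [(k, g["rho"].to_numpy()) for k, g in predictions.groupby(by)]
    order = {name: i for i, name in enumerate(CLASS_NAMES)}
    groups.sort(key=lambda kg: order.get(str(kg[0]), 99))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([g for _, g in groups], tick_labels=[str(k) for k, _ in groups])
    ax.axhline(0.5, color="gray", ls="--", lw=0.8)
    ax.set_ylabel(r"mean probability $\rho$ (pathologic)")
    ax.set_xlabel(by)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def score_plot(results, path: str) -> None:
    """LV1 vs LV2 score scatter colored by tissue class."""
    t1, _ = results.scores_loadings("LV1")
    t2, _ = results.scores_loadings("LV2")
    labels = np.array([lab.value for lab in results.model.labels])
    fig, ax = plt.subplots(figsize=(5, 5))
    for name in CLASS_NAMES:
        sel = labels == name
        ax.scatter(t1[sel], t2[sel], s=12, label=name, alpha=0.7)
    ax.set_xlabel("LV1 score")
    ax.set_ylabel("LV2 score")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def loading_plot(results, path: str) -> None:
    """LV1 and LV2 loadings against the wavenumber axis."""
    axis = results.model.axis
    if axis is None:
        axis = np.arange(results.x_loadings.shape[0])
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    for i, ax in enumerate(axes):
        _, loading = results.scores_loadings(f"LV{i + 1}")
        ax.plot(axis, loading, lw=0.8)
        ax.set_ylabel(f"LV{i + 1} loading")
        ax.axhline(0, color="gray", lw=0.5)
    axes[-1].set_xlabel(r"wavenumber (cm$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
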