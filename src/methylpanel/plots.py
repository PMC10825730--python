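"""Diagnostic figures: duplicate reproducibility and SVD association heat map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_duplicate_ks(pair_distances: pd.Series, ks_to_mean: pd.DataFrame,
                      path) -> None:
    """Pair KS distance (x) vs each member's distance to the average array (y)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for pair, d in pair_distances.items():
        for member in ks_to_mean.columns:
            ax.scatter(d, ks_to_mean.loc[pair, member], c="tab:blue", s=20)
    ax.axhline(0.6, ls="--", c="tab:red", lw=1, label="suspect threshold 0.6")
    ax.set_xlabel("duplicate pair KS distance")
    ax.set_ylabel("KS distance to average array")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_svd_heatmap(diagnostics: pd.DataFrame, path) -> None:
    """Heat map of component-vs-covariate association p-values."""
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(diagnostics.to_numpy(dtype=float), aspect="auto",
                   cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xticks(np.arange(diagnostics.shape[1]),
                  labels=diagnostics.columns, rotation=45, ha="right")
    ax.set_yticks(np.arange(diagnostics.shape[0]), labels=diagnostics.index)
    fig.colorbar(im, ax=ax, label="p-value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
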