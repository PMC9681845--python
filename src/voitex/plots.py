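"""Correlation-matrix figures for the reduction reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["plot_correlation_matrix"]


def plot_correlation_matrix(
    rho: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """Heatmap of a Spearman matrix, annotated with the coefficients."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.8 * len(rho) + 2, 0.8 * len(rho) + 1.5))
    im = ax.imshow(rho.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho.columns)))
    ax.set_xticklabels(rho.columns, rotation=90)
    ax.set_yticks(range(len(rho.index)))
    ax.set_yticklabels(rho.index)
    for i in range(len(rho)):
        for j in range(len(rho.columns)):
            v = rho.values[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Spearman rho")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
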