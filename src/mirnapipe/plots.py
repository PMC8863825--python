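"""Figure helpers: correlation heatmap, PCA biplot, volcano/MA plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pca import PCAResult
from .pheno import CorrMatrix

__all__ = ["correlation_heatmap", "pca_biplot", "volcano_plot", "ma_plot"]


def correlation_heatmap(corr: CorrMatrix, path: str | Path) -> Path:
    mat = corr.ordered()
    h = max(3.0, 0.22 * len(mat.index) + 1.5)
    w = max(4.0, 0.3 * len(mat.columns) + 2.0)
    fig, ax = plt.subplots(figsize=(w, h))
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman ρ")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def pca_biplot(
    result: PCAResult, groups: pd.Series, path: str | Path, n_arrows: int = 10
) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    groups = groups.reindex(result.scores.index)
    for g in dict.fromkeys(groups):
        sel = (groups == g).to_numpy()
        ax.scatter(
            result.scores.iloc[sel, 0], result.scores.iloc[sel, 1], s=14, label=g
        )
    top = (
        (result.contributions["PC1"] + result.contributions["PC2"])
        .sort_values(ascending=False)
        .head(n_arrows)
        .index
    )
    scale = 0.8 * np.abs(result.scores.iloc[:, :2].to_numpy()).max()
    for feat in top:
        lx, ly = result.loadings.loc[feat, ["PC1", "PC2"]]
        ax.annotate(
            feat,
            xy=(lx * scale, ly * scale),
            xytext=(0, 0),
            textcoords="data",
            arrowprops={"arrowstyle": "<-", "color": "0.4", "lw": 0.8},
            fontsize=6,
            color="0.25",
        )
    vf = result.variance_fractions
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}%)")
    ax.legend(title="group", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def volcano_plot(result: pd.DataFrame, path: str | Path, fdr: float = 0.05) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = result["FDR"] <= fdr
    y = -np.log10(result["FDR"].clip(lower=1e-300))
    ax.scatter(result.loc[~sig, "logFC"], y[~sig], s=6, c="0.6")
    ax.scatter(result.loc[sig, "logFC"], y[sig], s=8, c="crimson")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 FDR")
    ax.set_title(result.attrs.get("comparison", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ma_plot(result: pd.DataFrame, path: str | Path, fdr: float = 0.05) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = result["FDR"] <= fdr
    ax.scatter(result.loc[~sig, "logCPM"], result.loc[~sig, "logFC"], s=6, c="0.6")
    ax.scatter(result.loc[sig, "logCPM"], result.loc[sig, "logFC"], s=8, c="crimson")
    ax.axhline(0.0, color="0.3", lw=0.8)
    ax.set_xlabel("average log2 CPM")
    ax.set_ylabel("log2 fold-change")
    ax.set_title(result.attrs.get("comparison", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
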