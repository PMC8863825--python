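"""Principal component analysis of the combined miRNA + phenotype matrix.

The feature matrix concatenates log-CPM values of the differentially
expressed miRNAs with log-transformed phenotype parameters, z-scored per
column.  PCA is the singular value decomposition of that centered, scaled
matrix; eigenvalues are squared singular values over (n - 1), feature
contributions are squared loadings as percentages (the fviz-style
convention), and a deterministic sign rule makes results backend-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "build_feature_matrix",
    "run_pca",
    "top_contributors",
    "group_separation",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # feature x component, unit-norm columns
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    contributions: pd.DataFrame  # feature x component, percentages

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def build_feature_matrix(
    logcpm: pd.DataFrame,
    pheno: pd.DataFrame,
    log_pheno: bool = True,
    log_eps: float = 1.0,
) -> pd.DataFrame:
    """Sample x feature matrix: DE-miRNA log-CPM columns followed by
    phenotype columns, each z-scored (ddof=1).

    Phenotype columns that are entirely nonnegative are log-transformed as
    ``log(x + log_eps)``; columns with negative values (ratios, z-scaled
    scores) enter untransformed.  Missing entries are mean-imputed per
    column before scaling; zero-variance columns are dropped with a
    warning.
    """
    pheno_num = pheno.select_dtypes(include=[np.number])
    samples = [s for s in logcpm.columns if s in pheno_num.index]
    if len(samples) < 3:
        raise ValueError("need at least three shared samples")
    blocks = [logcpm[samples].T]
    phen = pheno_num.loc[samples].copy()
    if log_pheno:
        for col in phen.columns:
            vals = phen[col]
            if (vals.dropna() >= 0).all():
                phen[col] = np.log(vals + log_eps)
    blocks.append(phen)
    mat = pd.concat(blocks, axis=1)
    mat = mat.fillna(mat.mean(axis=0))
    sd = mat.std(axis=0, ddof=1)
    dropped = list(mat.columns[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
        mat = mat.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    return (mat - mat.mean(axis=0)) / sd


def run_pca(matrix: pd.DataFrame) -> PCAResult:
    """SVD-based PCA of an already centered/scaled sample x feature matrix.

    Components are ordered by nonincreasing eigenvalue; within each
    component the largest-magnitude loading is made positive (first such
    feature on ties).
    """
    x = matrix.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 samples and 2 features")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = s.size
    # deterministic sign: flip so the largest-|loading| entry is positive
    for c in range(k):
        pivot = int(np.argmax(np.abs(vt[c])))
        if vt[c, pivot] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    eigenvalues = s**2 / (n - 1)
    fractions = eigenvalues / eigenvalues.sum()
    comp = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=comp)
    scores = pd.DataFrame(u * s, index=matrix.index, columns=comp)
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        contributions=contrib,
    )


def top_contributors(
    result: PCAResult, k: int = 30, components: tuple[int, ...] = (1, 2)
) -> pd.DataFrame:
    """Features ranked by eigenvalue-weighted mean contribution over the
    selected components (1-based); returns all features when k exceeds the
    feature count."""
    cols = [f"PC{c}" for c in components]
    missing = [c for c in cols if c not in result.contributions.columns]
    if missing:
        raise ValueError(f"components not present: {missing}")
    lam = np.array([result.eigenvalues[c - 1] for c in components])
    weighted = (result.contributions[cols] * lam).sum(axis=1) / lam.sum()
    out = pd.DataFrame({"combined_contribution": weighted})
    out = out.join(result.contributions[cols])
    out = out.sort_values("combined_contribution", ascending=False, kind="stable")
    return out.head(min(k, len(out)))


def group_separation(
    scores: pd.DataFrame, groups: pd.Series, component: str = "PC1"
) -> dict:
    """How well one principal component separates the extreme groups.

    Reports per-group mean/SD on the component, the best threshold-classifier
    accuracy for the two groups with extreme means, and whether every other
    group's mean lies between those extremes.
    """
    groups = groups.reindex(scores.index)
    pc = scores[component]
    stats = {
        g: {"mean": float(pc[groups == g].mean()), "sd": float(pc[groups == g].std())}
        for g in dict.fromkeys(groups)
    }
    means = {g: s["mean"] for g, s in stats.items()}
    lo_g = min(means, key=means.get)
    hi_g = max(means, key=means.get)
    x = pc[(groups == lo_g) | (groups == hi_g)].to_numpy()
    y = (groups[(groups == lo_g) | (groups == hi_g)] == hi_g).to_numpy()
    accuracy = _best_threshold_accuracy(x, y)
    intermediate = {
        g: means[lo_g] < means[g] < means[hi_g]
        for g in means
        if g not in (lo_g, hi_g)
    }
    return {
        "component": component,
        "group_stats": stats,
        "extreme_groups": [lo_g, hi_g],
        "threshold_accuracy": accuracy,
        "intermediate_groups": intermediate,
    }


def _best_threshold_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    """Accuracy of the best 1-D threshold classifier (either direction)."""
    order = np.argsort(x, kind="stable")
    ys = y[order].astype(int)
    n = ys.size
    # threshold after position i: predict positive for x above it
    pos_right = np.concatenate([[ys.sum()], ys.sum() - np.cumsum(ys)])
    neg_left = np.concatenate([[0], np.cumsum(1 - ys)])
    correct_up = pos_right + neg_left
    correct_down = n - correct_up
    return float(np.max(np.maximum(correct_up, correct_down)) / n)
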