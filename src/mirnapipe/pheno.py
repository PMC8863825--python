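"""Spearman correlation of miRNA expression with physiological parameters,
and block ordering of the resulting correlation matrix.

Correlations are computed on TMM-normalized log-CPM (rank correlations on
raw counts would be confounded by library size).  Missing phenotype entries
are excluded pairwise; a pair needs at least three complete samples, and a
constant column yields an undefined (NaN) coefficient rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import rankdata

__all__ = ["CorrMatrix", "spearman_matrix", "block_order"]

MIN_PAIRS = 3


@dataclass
class CorrMatrix:
    rho: pd.DataFrame  # miRNA x parameter Spearman coefficients
    n_pairs: pd.DataFrame  # complete pairs behind each coefficient
    row_order: list[str] | None = None
    col_order: list[str] | None = None

    def ordered(self) -> pd.DataFrame:
        rows = self.row_order or list(self.rho.index)
        cols = self.col_order or list(self.rho.columns)
        return self.rho.loc[rows, cols]


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < MIN_PAIRS:
        return np.nan, n
    rx = rankdata(x[ok])
    ry = rankdata(y[ok])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return np.nan, n  # constant input: rho undefined, not zero
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry))), n


def spearman_matrix(logcpm: pd.DataFrame, pheno: pd.DataFrame) -> CorrMatrix:
    """Spearman rho of every (miRNA, parameter) pair.

    ``logcpm`` is miRNA x sample; ``pheno`` is sample x parameter and may
    contain NaN.  Non-numeric phenotype columns (e.g. a group label) are
    dropped.
    """
    pheno_num = pheno.select_dtypes(include=[np.number])
    samples = [s for s in logcpm.columns if s in pheno_num.index]
    if len(samples) < MIN_PAIRS:
        raise ValueError("need at least three shared samples")
    expr = logcpm[samples].to_numpy(dtype=float)
    phen = pheno_num.loc[samples].to_numpy(dtype=float)
    rho = np.empty((expr.shape[0], phen.shape[1]))
    npairs = np.empty_like(rho, dtype=int)
    for i in range(expr.shape[0]):
        for j in range(phen.shape[1]):
            rho[i, j], npairs[i, j] = _spearman_pair(expr[i], phen[:, j])
    return CorrMatrix(
        rho=pd.DataFrame(rho, index=logcpm.index, columns=pheno_num.columns),
        n_pairs=pd.DataFrame(
            npairs, index=logcpm.index, columns=pheno_num.columns
        ),
    )


def _leaf_order(profiles: pd.DataFrame) -> list[str]:
    if len(profiles) <= 2:
        return list(profiles.index)
    # sort by label first so the ordering is invariant to input permutation
    profiles = profiles.sort_index(kind="stable")
    z = linkage(profiles.to_numpy(dtype=float), method="average", metric="euclidean")
    return [profiles.index[i] for i in leaves_list(z)]


def block_order(corr: CorrMatrix) -> CorrMatrix:
    """Order rows and columns by average-linkage hierarchical clustering of
    their correlation profiles (Euclidean distance), exposing blocks of
    co-varying miRNAs/parameters.  NaN cells are replaced by 0 for distance
    purposes only."""
    filled = corr.rho.fillna(0.0)
    if filled.isna().any().any():
        raise ValueError("correlation matrix has fully-missing entries")
    return CorrMatrix(
        rho=corr.rho,
        n_pairs=corr.n_pairs,
        row_order=_leaf_order(filled),
        col_order=_leaf_order(filled.T),
    )
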