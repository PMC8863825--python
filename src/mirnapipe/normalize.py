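"""Expression filtering and TMM (trimmed mean of M-values) normalization.

The filter keeps a miRNA when its median-library-normalized count
(count / median library size x 1e6) reaches ``min_norm_count`` in at least
``ceil(min_sample_frac x n_smallest)`` samples, where ``n_smallest`` is the
size of the smallest group.  Two scopes are offered: ``"all"`` counts
qualifying samples anywhere in the cohort (the filterByExpr-style
convention, default) and ``"smallest"`` counts them inside the smallest
group only.

TMM follows the Robinson–Oshlack definition: reference sample by upper
quartile, gene-wise M/A values over doubly-positive genes, 30%/5% two-sided
trims on M and A, inverse-delta-method precision weights, factors rescaled
to geometric mean 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterSpec",
    "NormFactors",
    "filter_expressed",
    "tmm_factors",
    "log_cpm",
]


@dataclass(frozen=True)
class FilterSpec:
    min_norm_count: float = 10.0
    min_sample_frac: float = 0.7
    scope: str = "all"  # "all" | "smallest"

    def __post_init__(self) -> None:
        if self.min_norm_count <= 0:
            raise ValueError("min_norm_count must be > 0")
        if not 0 < self.min_sample_frac <= 1:
            raise ValueError("min_sample_frac must lie in (0, 1]")
        if self.scope not in ("all", "smallest"):
            raise ValueError("scope must be 'all' or 'smallest'")


@dataclass
class NormFactors:
    """Per-sample TMM factors; effective library = library size x factor."""

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = float(np.log(self.factors).mean())
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def smallest_group_quota(groups: pd.Series, min_sample_frac: float = 0.7) -> int:
    sizes = groups.value_counts()
    if (sizes == 0).any() or len(sizes) < 2:
        raise ValueError("at least two non-empty groups are required")
    return math.ceil(min_sample_frac * int(sizes.min()))


def filter_expressed(
    counts: pd.DataFrame, groups: pd.Series, spec: FilterSpec = FilterSpec()
) -> list[str]:
    """Retained miRNA ids, input order preserved."""
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    quota = smallest_group_quota(groups, spec.min_sample_frac)
    norm = counts / float(lib.median()) * 1e6
    passing = norm >= spec.min_norm_count
    if spec.scope == "smallest":
        smallest = groups.value_counts().idxmin()
        passing = passing.loc[:, (groups == smallest).to_numpy()]
    keep = passing.sum(axis=1) >= quota
    return list(counts.index[keep.to_numpy()])


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array(
        [np.quantile(counts[:, j], p) / lib[j] for j in range(counts.shape[1])]
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        raise ValueError("sample shares no positive genes with the TMM reference")
    M = np.log2((obs / lib_obs) / (ref / lib_ref))
    A = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    # asymptotic variance of M (delta method on binomial counts)
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = M.size
    loL = math.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = math.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rM = _rank(M)
    rA = _rank(A)
    keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
    if not keep.any():
        return 0.0
    return float(np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based (midranks for ties)."""
    from scipy.stats import rankdata

    return rankdata(x)


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> NormFactors:
    """TMM normalization factors for every sample.

    ``reference`` picks the reference sample explicitly; by default it is
    the sample whose 75th-percentile count-to-library ratio is closest to
    the mean of those ratios.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    if reference is None:
        f75 = _quantile_factor(x, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(reference)
    log2f = np.array(
        [
            _tmm_pair(
                x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, sum_trim,
            )
            for j in range(x.shape[1])
        ]
    )
    f = 2.0**log2f
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(
        factors=pd.Series(f, index=counts.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=counts.columns, name="lib_size"),
    )


def log_cpm(
    counts: pd.DataFrame, factors: NormFactors, prior: float = 2.0
) -> pd.DataFrame:
    """log2 counts-per-million on effective libraries with a library-scaled
    prior count: ``log2((y + prior_j) / (lib_j + 2 prior_j) * 1e6)`` where
    ``prior_j = prior x lib_j / mean(lib)``."""
    lib = factors.effective_lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    prior_j = prior * lib / lib.mean()
    y = counts.to_numpy(dtype=float)
    out = np.log2((y + prior_j[None, :]) / (lib + 2 * prior_j)[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
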