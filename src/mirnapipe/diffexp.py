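"""Negative-binomial exact-test differential expression.

Model: count of miRNA i in sample j ~ NB(mean, phi) with a single common
dispersion phi (Var = mu + phi mu^2).  The workflow is the classic
count-based exact-test path:

1. equalize effective library sizes by a quantile-to-quantile NB transform
   onto the geometric-mean library (pseudo-counts);
2. estimate the common dispersion by conditional maximum likelihood on the
   equalized counts (likelihood of within-group counts given group sums);
3. for each pair of groups, condition on the total pseudo-count: under the
   null the group-A sum given the total follows a beta-binomial
   (binomial in the Poisson limit); the two-sided p-value doubles the
   smaller tail, capped at 1;
4. Benjamini–Hochberg adjustment per comparison, discovery union across
   comparisons at the FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm as norm_dist

from .normalize import NormFactors, tmm_factors

__all__ = [
    "DispersionEstimate",
    "bh_adjust",
    "equalize_lib_sizes",
    "estimate_common_dispersion",
    "exact_test",
    "run_all_comparisons",
]

_MAX_PHI = 50.0
_MIN_PHI = 1e-6


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str = "qCML-common"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# library-size equalization (quantile-to-quantile NB transform)
# ---------------------------------------------------------------------------


def _q2qnbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, phi: float
) -> np.ndarray:
    """Map counts with per-cell mean ``input_mean`` to equivalent quantiles
    of an NB with mean ``output_mean``, averaging a normal and a gamma
    continuous approximation."""
    eps = 1e-14
    zero = (input_mean < eps) | (output_mean < eps)
    mi = np.where(zero, input_mean + 0.25, input_mean)
    mo = np.where(zero, output_mean + 0.25, output_mean)
    vi = mi * (1.0 + phi * mi)
    vo = mo * (1.0 + phi * mo)
    upper = x >= mi

    p_norm = np.where(
        upper,
        norm_dist.sf(x, loc=mi, scale=np.sqrt(vi)),
        norm_dist.cdf(x, loc=mi, scale=np.sqrt(vi)),
    )
    p_norm = np.clip(p_norm, 1e-300, 1.0)
    q_norm = np.where(
        upper,
        norm_dist.isf(p_norm, loc=mo, scale=np.sqrt(vo)),
        norm_dist.ppf(p_norm, loc=mo, scale=np.sqrt(vo)),
    )

    shape_i, scale_i = mi**2 / vi, vi / mi
    shape_o, scale_o = mo**2 / vo, vo / mo
    p_gam = np.where(
        upper,
        gamma_dist.sf(x, a=shape_i, scale=scale_i),
        gamma_dist.cdf(x, a=shape_i, scale=scale_i),
    )
    p_gam = np.clip(p_gam, 1e-300, 1.0)
    q_gam = np.where(
        upper,
        gamma_dist.isf(p_gam, a=shape_o, scale=scale_o),
        gamma_dist.ppf(p_gam, a=shape_o, scale=scale_o),
    )
    return np.maximum(0.0, (q_norm + q_gam) / 2.0)


def equalize_lib_sizes(
    counts: pd.DataFrame, eff_lib: pd.Series, phi: float
) -> tuple[pd.DataFrame, float]:
    """Pseudo-counts on a common (geometric-mean) library size."""
    lib = eff_lib.reindex(counts.columns).to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(lib))))
    y = counts.to_numpy(dtype=float)
    prop = y.sum(axis=1) / lib.sum()
    input_mean = np.outer(prop, lib)
    output_mean = np.outer(prop, np.full(len(lib), common))
    pseudo = _q2qnbinom(y, input_mean, output_mean, phi)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood)
# ---------------------------------------------------------------------------


def _cond_loglik(pseudo_by_group: list[np.ndarray], phi: float) -> float:
    """Sum over genes/groups of the NB conditional log-likelihood of
    within-group counts given the group sum (library sizes equalized)."""
    r = 1.0 / phi
    total = 0.0
    for y in pseudo_by_group:
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r))
            - n * y.shape[0] * gammaln(r)
            + np.sum(gammaln(n * r) - gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: NormFactors,
    n_iter: int = 2,
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    Alternates pseudo-count equalization and 1-D maximization of the
    conditional log-likelihood (coarse log-scale grid, then bounded
    golden-section/parabolic refinement); phi constrained to
    [1e-6, 50].  Groups with a single sample carry no information and are
    ignored.
    """
    groups = groups.reindex(counts.columns)
    sizes = groups.value_counts()
    informative = [g for g, n in sizes.items() if n >= 2]
    if not informative:
        raise ValueError("no replication: every group is a singleton")
    phi = 0.01
    grid = np.concatenate([[_MIN_PHI], np.logspace(-4, np.log10(_MAX_PHI), 25)])
    for _ in range(n_iter):
        pseudo, _ = equalize_lib_sizes(counts, factors.effective_lib_sizes, phi)
        blocks = [
            pseudo.loc[:, (groups == g).to_numpy()].to_numpy(dtype=float)
            for g in informative
        ]
        ll = np.array([_cond_loglik(blocks, g) for g in grid])
        best = int(np.argmax(ll))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if lo == hi:
            phi = float(grid[best])
        else:
            res = minimize_scalar(
                lambda g: -_cond_loglik(blocks, g),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-6},
            )
            phi = float(np.clip(res.x, _MIN_PHI, _MAX_PHI))
    return DispersionEstimate(phi=phi)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def _cond_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log pmf of the group-A sum given total t under the null.

    Sums of n i.i.d. NB(mu, phi) are NB with size n/phi and the same
    success probability, so the conditional law is beta-binomial
    BB(t, n_a/phi, n_b/phi); in the Poisson limit it is
    Binomial(t, n_a/(n_a+n_b)).
    """
    s = np.arange(t + 1, dtype=float)
    logchoose = gammaln(t + 1) - gammaln(s + 1) - gammaln(t - s + 1)
    if phi < 1e-10:
        pa = n_a / (n_a + n_b)
        return logchoose + s * np.log(pa) + (t - s) * np.log1p(-pa)
    a, b = n_a / phi, n_b / phi
    return logchoose + betaln(s + a, t - s + b) - betaln(a, b)


def _double_tail_p(t: int, s_obs: int, n_a: int, n_b: int, phi: float) -> float:
    logpmf = _cond_logpmf(t, n_a, n_b, phi)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    lower = pmf[: s_obs + 1].sum()
    upper = pmf[s_obs:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    dispersion: DispersionEstimate,
    factors: NormFactors,
    prior_count: float = 0.125,
    comparison: str | None = None,
) -> pd.DataFrame:
    """Exact NB test of group B against group A for every miRNA.

    Returns a frame with ``logFC`` (B relative to A), ``logCPM``,
    ``PValue`` and ``FDR`` columns, indexed like ``counts``.
    """
    groups = groups.reindex(counts.columns)
    cols_a = counts.columns[(groups == group_a).to_numpy()]
    cols_b = counts.columns[(groups == group_b).to_numpy()]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both groups must be non-empty")
    sub = counts.loc[:, list(cols_a) + list(cols_b)]
    pseudo, common_lib = equalize_lib_sizes(
        sub, factors.effective_lib_sizes.loc[sub.columns], dispersion.phi
    )
    n_a, n_b = len(cols_a), len(cols_b)
    sum_a = np.rint(pseudo[cols_a].sum(axis=1).to_numpy()).astype(np.int64)
    sum_b = np.rint(pseudo[cols_b].sum(axis=1).to_numpy()).astype(np.int64)

    pvals = np.ones(len(sub))
    for i, (sa, sb) in enumerate(zip(sum_a, sum_b)):
        t = int(sa + sb)
        if t == 0:
            continue
        pvals[i] = _double_tail_p(t, int(sa), n_a, n_b, dispersion.phi)

    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    logfc = np.log2(mean_b + prior_count) - np.log2(mean_a + prior_count)
    mean_all = (sum_a + sum_b) / (n_a + n_b)
    logcpm = np.log2((mean_all + 2.0) / (common_lib + 4.0) * 1e6)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": logcpm,
            "PValue": pvals,
            "FDR": bh_adjust(pvals),
        },
        index=sub.index,
    )
    out.attrs["comparison"] = comparison or f"{group_b}_vs_{group_a}"
    return out


def run_all_comparisons(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: NormFactors | None = None,
    dispersion: DispersionEstimate | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """All pairwise exact tests plus the union of discoveries.

    Comparisons follow group first-appearance order: (g2 vs g1),
    (g3 vs g1), (g3 vs g2), ...; the union lists miRNAs with
    FDR <= threshold in any comparison, in count-matrix order.
    """
    groups = groups.reindex(counts.columns)
    ordered = list(dict.fromkeys(groups))
    if len(ordered) < 2:
        raise ValueError("at least two groups are required")
    if factors is None:
        factors = tmm_factors(counts)
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, groups, factors)
    results: dict[str, pd.DataFrame] = {}
    for i in range(1, len(ordered)):
        for j in range(i):
            a, b = ordered[j], ordered[i]
            label = f"{b}_vs_{a}"
            results[label] = exact_test(
                counts, groups, a, b, dispersion, factors, comparison=label
            )
    significant = set()
    for res in results.values():
        significant.update(res.index[res["FDR"] <= fdr_threshold])
    union = [m for m in counts.index if m in significant]
    return results, union
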