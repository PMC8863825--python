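"""Independent reference implementations used only as test oracles.

Each routine here is deliberately written from the defining formulas, by a
different route than the package (brute-force scans, explicit convolution,
literal step-by-step transcriptions), so that agreement is evidence rather
than tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import nbinom, rankdata


def bruteforce_alignments(
    read: str, precursors: dict[str, str], max_mismatches: int
) -> set[tuple[str, int, int]]:
    """All end-to-end hits of ``read`` by scanning every offset of every
    precursor and counting Hamming mismatches."""
    hits = set()
    for pid, seq in precursors.items():
        for start in range(0, len(seq) - len(read) + 1):
            mm = sum(a != b for a, b in zip(read, seq[start : start + len(read)]))
            if mm <= max_mismatches:
                hits.add((pid, start, mm))
    return hits


def bruteforce_best_stratum(
    read: str, precursors: dict[str, str], max_mismatches: int
) -> set[tuple[str, int, int]]:
    hits = bruteforce_alignments(read, precursors, max_mismatches)
    if not hits:
        return set()
    best = min(mm for _, _, mm in hits)
    return {h for h in hits if h[2] == best}


def nb_sum_pmf(total: int, n_samples: int, mu: float, phi: float) -> np.ndarray:
    """pmf of the sum of ``n_samples`` i.i.d. NB(mu, phi) variables on
    0..total, by explicit repeated convolution of the single-variable pmf."""
    if phi == 0:
        # Poisson limit via NB with a huge size parameter
        phi = 1e-12
    size = 1.0 / phi
    p = size / (size + mu)
    single = nbinom.pmf(np.arange(total + 1), size, p)
    out = single.copy()
    for _ in range(n_samples - 1):
        out = np.convolve(out, single)[: total + 1]
    return out


def exact_test_p_enumeration(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float, mu: float = 5.0
) -> float:
    """Two-sided exact-test p-value by exhaustive enumeration: conditional
    probabilities of every split of the total from NB-sum pmfs, then the
    doubled smaller tail."""
    t = sum_a + sum_b
    pa = nb_sum_pmf(t, n_a, mu, phi)
    pb = nb_sum_pmf(t, n_b, mu, phi)
    joint = pa * pb[::-1]
    joint = joint / joint.sum()
    lower = joint[: sum_a + 1].sum()
    upper = joint[sum_a:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def tmm_factors_literal(counts: np.ndarray) -> np.ndarray:
    """Literal step-by-step transcription of the trimmed-mean-of-M-values
    definition with plain Python loops (30% M trim, 5% A trim,
    inverse-variance weights, geometric-mean-1 rescaling)."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    # reference: sample whose 75th count/lib quantile is closest to the mean
    f75 = [np.quantile(counts[:, j], 0.75) / lib[j] for j in range(n_samples)]
    ref = min(range(n_samples), key=lambda j: abs(f75[j] - np.mean(f75)))

    log2f = []
    for j in range(n_samples):
        M, A, w = [], [], []
        for i in range(n_genes):
            yo, yr = counts[i, j], counts[i, ref]
            if yo > 0 and yr > 0:
                po, pr = yo / lib[j], yr / lib[ref]
                M.append(math.log2(po / pr))
                A.append(0.5 * math.log2(po * pr))
                w.append(
                    (lib[j] - yo) / (lib[j] * yo) + (lib[ref] - yr) / (lib[ref] * yr)
                )
        M, A, w = np.array(M), np.array(A), np.array(w)
        if M.size == 0 or np.max(np.abs(M)) < 1e-6:
            log2f.append(0.0)
            continue
        n = M.size
        loL, loS = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
        rM, rA = rankdata(M), rankdata(A)
        keep = (
            (rM >= loL)
            & (rM <= n + 1 - loL)
            & (rA >= loS)
            & (rA <= n + 1 - loS)
        )
        if not keep.any():
            log2f.append(0.0)
            continue
        num = sum(M[k] / w[k] for k in np.nonzero(keep)[0])
        den = sum(1.0 / w[k] for k in np.nonzero(keep)[0])
        log2f.append(num / den)
    f = np.array([2.0**v for v in log2f])
    return f / np.exp(np.mean(np.log(f)))


def bh_literal(pvalues: list[float]) -> list[float]:
    """Step-up BH by the definition: sort, q_(i) = min_{j>=i} min(1, p_(j) m/j)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = []
    for i in range(m):
        q_sorted.append(
            min(
                min(1.0, pvalues[order[j]] * m / (j + 1))
                for j in range(i, m)
            )
        )
    out = [0.0] * m
    for rank_pos, idx in enumerate(order):
        out[idx] = q_sorted[rank_pos]
    return out
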