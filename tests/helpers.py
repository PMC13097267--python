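"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's vectorized implementations: Otsu by
an explicit loop over every cut, AUC by pair counting, Youden by exhaustive
cutoff search, Mann-Whitney by full rank-permutation enumeration.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def otsu_bruteforce(edges: np.ndarray, counts: np.ndarray) -> float:
    """Scan every interior bin edge; maximize between-class variance."""
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (np.asarray(edges[:-1], dtype=float) + np.asarray(edges[1:], dtype=float))
    best_sigma, best_t = -np.inf, None
    for i in range(len(counts) - 1):  # low class = bins 0..i
        w0 = counts[: i + 1].sum()
        w1 = counts[i + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (counts[i + 1 :] * centers[i + 1 :]).sum() / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        # ties keep the smaller threshold; plateaus over empty bins are
        # mathematically tied but differ in the last ulp, hence the tolerance
        if sigma > best_sigma + 1e-12 * max(best_sigma, 1.0):
            best_sigma, best_t = sigma, edges[i + 1]
    return float(best_t)


def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance fraction over all (positive, negative) pairs, ties half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(scores: np.ndarray, labels: np.ndarray, direction: str) -> tuple[float, float, float]:
    """Exhaustive Youden search over observed scores; ties to higher specificity."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for c in np.unique(scores):
        if direction == "greater_is_positive":
            sens, spec = np.mean(pos > c), np.mean(neg <= c)
            pref = c
        else:
            sens, spec = np.mean(pos <= c), np.mean(neg > c)
            pref = -c
        key = (sens + spec - 1.0, spec, pref)
        if best is None or key > best[0]:
            best = (key, float(c), 100 * sens, 100 * spec)
    return best[1], best[2], best[3]


def mannwhitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all rank assignments (tie-free data)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    m = n1 * n2
    center = m / 2.0
    d_obs = abs(u_obs - center)
    hits = 0
    idx = range(n1 + n2)
    for pick in combinations(idx, n1):
        u = ranks[list(pick)].sum() - n1 * (n1 + 1) / 2
        if abs(u - center) >= d_obs - 1e-12:
            hits += 1
    return hits / comb(n1 + n2, n1)


def icc21_variance_components(x: np.ndarray) -> float:
    """ICC(2,1) point estimate from explicit two-way ANOVA sums of squares."""
    n, k = x.shape
    grand = x.mean()
    ssr = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ssc = n * ((x.mean(axis=0) - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
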