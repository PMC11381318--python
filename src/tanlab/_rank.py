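"""Rank-based two-sample and paired tests.

The two-sample comparison is the Dunn-type rank z: observations of both groups
are pooled and mid-ranked, and the difference in mean ranks is divided by its
null standard error with tie correction,

    z = (R̄_x − R̄_y) / sqrt( (N(N+1)/12 − T/(12(N−1))) (1/n_x + 1/n_y) ),

with T = Σ(t³ − t) over tie groups. This z is identical to the tie-corrected
Mann–Whitney normal deviate. The normal approximation is poor for very small
groups (its two-sided p can differ from the exact enumeration by > 0.2 below
n = 4), so p-values are computed by exact enumeration of the rank-sum null
distribution when both groups are small and tie-free, and from the normal
approximation otherwise.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb, erf, sqrt

import numpy as np
from scipy.stats import rankdata

#: largest per-group size at which method='auto' uses exact enumeration
EXACT_MAX_N = 10


def _norm_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_z(x, y) -> float:
    """Tie-corrected Dunn rank z; positive when x tends larger than y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    N = n1 + n2
    ranks = rankdata(pooled)
    var = (N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))) \
        * (1.0 / n1 + 1.0 / n2) if N > 1 else 0.0
    if var <= 0:
        return 0.0
    return float((ranks[:n1].mean() - ranks[n1:].mean()) / sqrt(var))


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Null distribution of the Mann–Whitney U statistic (no ties): number of
    arrangements yielding each U in 0..n1*n2."""
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def exact_u_p(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p of U by enumeration: 2·min(P(U≤u), P(U≥u)), capped."""
    counts = np.array(_u_counts(n1, n2), float)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    k = int(np.floor(u + 1e-9))
    lo = cdf[k]
    hi = 1.0 - (cdf[k - 1] if k > 0 else 0.0)
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample rank test; returns (z, two-sided p).

    method='normal' always uses the normal approximation; 'exact' enumerates
    the tie-free U null distribution (raises on ties); 'auto' uses exact when
    both groups have at most ``EXACT_MAX_N`` tie-free observations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    z = rank_z(x, y)

    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    use_exact = method == "exact" or (
        method == "auto" and not has_ties and max(n1, n2) <= EXACT_MAX_N)
    if use_exact:
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        r1 = rankdata(np.concatenate([x, y]))[:n1].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        return z, exact_u_p(u, n1, n2)
    if method not in ("auto", "normal"):
        raise ValueError(f"unknown method {method!r}")
    return z, min(1.0, 2.0 * _norm_sf(abs(z)))


def signed_rank(x, y, method: str = "auto") -> tuple[float, float, int]:
    """Paired (Wilcoxon signed-rank) test; returns (z, two-sided p, n used).

    Zero differences are dropped. z is the normal deviate of W+ with tie
    correction; for n ≤ 12 tie-free differences, p is computed by exact
    enumeration of the 2^n sign assignments.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    absr = rankdata(np.abs(d))
    w_plus = float(absr[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    z = 0.0 if var <= 0 else (w_plus - mu) / sqrt(var)

    no_ties = len(counts) == n
    if (method == "exact" or (method == "auto" and n <= 12)) and no_ties:
        # enumerate all sign assignments of the ranked magnitudes
        stats = np.zeros(1)
        for r in absr:
            stats = np.concatenate([stats, stats + r])
        lo = float(np.mean(stats <= w_plus + 1e-9))
        hi = float(np.mean(stats >= w_plus - 1e-9))
        return z, min(1.0, 2.0 * min(lo, hi)), n
    return z, min(1.0, 2.0 * _norm_sf(abs(z))), n
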