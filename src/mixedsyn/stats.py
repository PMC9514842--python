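"""Rank-based statistics with the reporting conventions used for the
recordings: Spearman rank correlation reported with df = n - 2, Mann-Whitney
U reported as the smaller of the two U statistics, and semi-log linear
trends. Two-sided p-values throughout; ties handled by midranks. Exact
p-values are enumerated for small samples (all rank permutations for
Spearman at n <= 8, all group assignments for the U test at n1 + n2 <= 12),
where the asymptotic approximations are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["CorrelationResult", "UTestResult", "spearman_rank", "mann_whitney_u",
           "semilog_trend", "SIGNIFICANCE_LEVEL"]

#: conventional significance threshold
SIGNIFICANCE_LEVEL = 0.05

_EXACT_SPEARMAN_N = 8
_EXACT_U_N = 12


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with the df = n - 2 reporting convention."""

    rho: float
    df: int
    n: int
    p: float
    exact: bool

    def __str__(self):
        return f"rho({self.df}) = {self.rho:.3f}, p = {self.p:.4g}, n = {self.n}"


@dataclass(frozen=True)
class UTestResult:
    """Mann-Whitney U (the smaller of U_a, U_b) with both group sizes."""

    U: float
    n1: int
    n2: int
    p: float
    exact: bool

    def __str__(self):
        return f"U = {self.U:g}, p = {self.p:.4g}, n1 = {self.n1}, n2 = {self.n2}"


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    # Pearson correlation of midranks; robust to ties
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def spearman_rank(x, y) -> CorrelationResult:
    """Spearman rank correlation on midranks, two-sided p-value.

    For n <= 8 the p-value is exact, by enumerating the permutation
    distribution of rho over all n! orderings of one variable; for larger n
    the usual t approximation with df = n - 2 is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= _EXACT_SPEARMAN_N:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            r = _rho_from_ranks(rx, np.asarray(perm))
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
        exact = True
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(tstat), df=n - 2))
        exact = False
    return CorrelationResult(rho=rho, df=n - 2, n=n, p=min(p, 1.0), exact=exact)


def _u_stats(pooled_ranks: np.ndarray, idx_a, n1: int, n2: int) -> float:
    ra = pooled_ranks[list(idx_a)].sum()
    return ra - n1 * (n1 + 1) / 2.0


def mann_whitney_u(a, b) -> UTestResult:
    """Mann-Whitney U test, two-sided, U = min(U_a, U_b), midrank ties.

    Exact p by enumerating all C(n1+n2, n1) group assignments of the pooled
    (mid)ranks when n1 + n2 <= 12; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = _u_stats(ranks, range(n1), n1, n2)
    u_b = n1 * n2 - u_a
    u = min(u_a, u_b)
    mid = n1 * n2 / 2.0

    if n1 + n2 <= _EXACT_U_N:
        dev = abs(u_a - mid) - 1e-12
        count = 0
        total = comb(n1 + n2, n1)
        for idx in combinations(range(n1 + n2), n1):
            ua = _u_stats(ranks, idx, n1, n2)
            if abs(ua - mid) >= dev:
                count += 1
        p = count / total
        exact = True
    else:
        # normal approximation with tie correction
        nn = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        sigma2 = n1 * n2 / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mid) - 0.5) / np.sqrt(sigma2)
            p = float(2.0 * sps.norm.sf(max(z, 0.0)))
        exact = False
    return UTestResult(U=float(u), n1=n1, n2=n2, p=min(p, 1.0), exact=exact)


def semilog_trend(x, y) -> tuple[float, float]:
    """Ordinary least squares of y against log10(x): (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if np.any(x <= 0):
        raise ValueError("semi-log trend requires strictly positive x")
    slope, intercept = np.polyfit(np.log10(x), y, 1)
    return float(slope), float(intercept)
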