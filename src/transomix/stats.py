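"""Statistical primitives: Welch's t, Storey/BH q-values, one-tailed Fisher.

These are the building blocks of responsiveness calling (Welch + Storey q)
and of motif/pathway enrichment (one-tailed Fisher + BH q).  Conventions for
degenerate inputs are deliberate and documented per function.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)

#: largest population size for which the Fisher tail is summed exactly in
#: integer arithmetic; beyond this scipy's hypergeometric sf is used.
_EXACT_FISHER_MAX_N = 500


class WelchResult(NamedTuple):
    statistic: float
    df: float
    p: float


def welch_test(a, b) -> WelchResult:
    """Two-tailed Welch's t-test with Satterthwaite degrees of freedom.

    Degenerate cases follow a strict contract: if both groups are constant
    with equal values the test is uninformative and p = 1 by convention; if
    either group has fewer than 2 non-missing values, or both groups are
    constant but unequal, the result is undefined (NaN) and the caller is
    expected to flag the molecule.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return WelchResult(math.nan, math.nan, math.nan)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, math.nan, 1.0)
        return WelchResult(math.nan, math.nan, math.nan)
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        (sa**2 / (a.size - 1) if sa else 0.0) + (sb**2 / (b.size - 1) if sb else 0.0)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), min(p, 1.0))


# ---------------------------------------------------------------------------
# False discovery rate
# ---------------------------------------------------------------------------


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_qvalues(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (via statsmodels)."""
    p = _check_pvalues(p)
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(p, *, fixed_lambda: float | None = None, lambdas=None) -> float:
    """Estimate the null proportion pi0.

    Default: evaluate pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a
    grid (0.05..0.95 step 0.05), fit a cubic smoother, and take the fitted
    value at the largest lambda, clamped to (0, 1].  With ``fixed_lambda``
    the single-point estimate at that lambda is returned (exactly testable).
    """
    p = _check_pvalues(p)
    m = p.size
    if fixed_lambda is not None:
        if not 0 <= fixed_lambda < 1:
            raise ValueError("fixed_lambda must lie in [0, 1)")
        pi0 = np.sum(p > fixed_lambda) / (m * (1.0 - fixed_lambda))
        return float(min(max(pi0, 1.0 / m), 1.0))
    grid = DEFAULT_LAMBDA_GRID if lambdas is None else np.asarray(lambdas, dtype=float)
    pi0_grid = np.array([np.sum(p > lam) / (m * (1.0 - lam)) for lam in grid])
    # cubic smoother over the grid, evaluated at the largest lambda
    coef = np.polyfit(grid, pi0_grid, deg=3)
    pi0 = float(np.polyval(coef, grid.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p, *, pi0: float | None = None, fixed_lambda: float | None = None) -> np.ndarray:
    """Storey q-values: q_(i) = min_{j >= i} pi0 * m * p_(j) / j on sorted p.

    With ``pi0=1`` this reduces exactly to Benjamini–Hochberg.  Input order
    is preserved in the output.
    """
    p = _check_pvalues(p)
    m = p.size
    if pi0 is None:
        pi0 = storey_pi0(p, fixed_lambda=fixed_lambda)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# One-tailed Fisher (enrichment direction)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _comb_table(n_max: int):
    table = [[0] * (n_max + 1) for _ in range(n_max + 1)]
    for n in range(n_max + 1):
        for k in range(n + 1):
            table[n][k] = math.comb(n, k)
    return table


def hypergeom_sf_exact(a: int, N: int, K: int, n: int) -> float:
    """P[X >= a] for X ~ Hypergeometric(N, K, n), exact integer tail sum."""
    lo = max(0, K + n - N)
    hi = min(K, n)
    if a <= lo:
        return 1.0
    if a > hi:
        return 0.0
    if N <= _EXACT_FISHER_MAX_N:
        C = _comb_table(_EXACT_FISHER_MAX_N)
        num = sum(C[K][x] * C[N - K][n - x] for x in range(a, hi + 1))
        return num / C[N][n]
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(a, hi + 1))
    # int/int division is correctly rounded in Python even for huge operands
    return num / math.comb(N, n)


class FisherResult(NamedTuple):
    odds_ratio: float
    p: float


def fisher_enrichment(k_in: int, n_in: int, k_total: int, n_total: int) -> FisherResult:
    """One-tailed (enrichment) Fisher's exact test on a 2x2 table.

    Parameters are set-overlap counts: ``k_in`` hits among the ``n_in``
    elements of the foreground set, ``k_total`` hits among the ``n_total``
    elements of the background universe (foreground included).  Returns the
    sample odds ratio of the 2x2 table (zero cells yield exact 0 or inf; no
    continuity correction) and P[X >= k_in] under the hypergeometric null.
    """
    if n_in <= 0 or n_total <= 0:
        raise ValueError("foreground and background must be non-empty")
    if not (0 <= k_in <= n_in <= n_total and k_in <= k_total <= n_total):
        raise ValueError("inconsistent 2x2 table counts")
    a = k_in
    b = n_in - k_in
    c = k_total - k_in
    d = (n_total - n_in) - c
    if d < 0:
        raise ValueError("more background hits than background elements")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan  # doubly degenerate table: 0/0
    if n_total <= _EXACT_FISHER_MAX_N:
        p = hypergeom_sf_exact(a, n_total, k_total, n_in)
    else:
        p = float(sps.hypergeom.sf(a - 1, n_total, k_total, n_in))
    return FisherResult(odds, min(max(p, 0.0), 1.0))
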