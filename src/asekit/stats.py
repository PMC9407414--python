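"""Exact and asymptotic tests used by every downstream stage.

All two-sided exact p-values follow the minimum-likelihood ("minlike")
convention: the p-value sums the probabilities of all outcomes whose point
probability does not exceed that of the observed outcome. At a symmetric
null (binomial p0 = 0.5) this coincides with the doubled-tail definition.
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "binom_exact_two_sided",
    "fisher_exact_two_sided",
    "bh_fdr",
    "chi2_yates_2x2",
    "two_proportion_z",
    "log2_ratio",
]


class TestResult(NamedTuple):
    """A test statistic (NaN when the test defines none) and its p-value."""

    statistic: float
    p_value: float


def binom_exact_two_sided(x: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-sided exact binomial test of H0: success probability = ``p0``.

    Parameters
    ----------
    x : int
        Number of successes, ``0 <= x <= n``.
    n : int
        Number of trials, ``n >= 1``.
    p0 : float
        Null success probability (default 0.5, the equal-proportion null
        used for allelic read counts).

    Returns
    -------
    TestResult
        ``statistic`` is the observed proportion ``x / n``.
    """
    if n < 1:
        raise ValueError(f"need at least one trial, got n={n}")
    if not 0 <= x <= n:
        raise ValueError(f"successes x={x} outside [0, {n}]")
    res = sps.binomtest(int(x), int(n), p=p0, alternative="two-sided")
    return TestResult(x / n, float(res.pvalue))


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    A table with any zero margin carries no information about association;
    by convention it returns p = 1.0 with a warning (statistic NaN).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(np.int64)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("2x2 table has a zero margin; returning p = 1.0")
        return TestResult(math.nan, 1.0)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_yates_2x2(table) -> TestResult:
    """2x2 chi-square test with Yates' continuity correction.

    statistic = sum over cells of max(|O - E| - 0.5, 0)^2 / E, with the
    expected counts from the row/column margins; p-value from the upper
    tail of the chi-square distribution with 1 degree of freedom. The
    correction is clamped at zero so near-null tables are never inflated.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    total = t.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("2x2 table has a zero margin")
    expected = np.outer(rows, cols) / total
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float(np.sum(adj**2 / expected))
    return TestResult(stat, float(sps.chi2.sf(stat, df=1)))


def two_proportion_z(
    p_expected: float, n1: int, x2: int, n2: int
) -> TestResult:
    """Two-tailed z-test comparing an expected proportion with an observed one.

    The expected side contributes a pseudo-count of successes
    ``x1 = p_expected * n1`` over the gene universe of size ``n1`` (kept
    unrounded); the observed side is ``x2`` successes out of ``n2``. The
    pooled estimate is ``(x1 + x2) / (n1 + n2)`` and

        z = (p_expected - x2/n2) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)).
    """
    if not 0 < p_expected < 1:
        raise ValueError("p_expected must lie strictly within (0, 1)")
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not 0 <= x2 <= n2:
        raise ValueError(f"x2={x2} outside [0, {n2}]")
    x1 = p_expected * n1
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0 or pooled >= 1:
        raise ValueError("pooled proportion degenerate (0 or 1)")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p_expected - x2 / n2) / se
    return TestResult(z, float(2 * sps.norm.sf(abs(z))))


def log2_ratio(a: float, b: float) -> float:
    """log2(a / b); both inputs must be positive.

    Upstream pseudocounting guarantees positivity — a nonpositive input
    here signals a missed pseudocount, so it is an error rather than inf.
    """
    if a <= 0 or b <= 0:
        raise ValueError(
            f"log2_ratio requires positive counts, got ({a}, {b}); "
            "was the zero-count pseudocount applied?"
        )
    return math.log2(a / b)
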