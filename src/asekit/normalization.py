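"""Between-column TMM scaling, integer normalized counts, and the
low-expression filter with zero-count pseudocounting.

TMM (trimmed mean of M-values) estimates one scaling factor per count
column from a doubly trimmed, inverse-variance-weighted mean of per-gene
log2 expression ratios against a reference column, so that columns differing
only in sequencing depth or in the expression of a minority of genes are
brought to a common scale. Downstream exact tests need integer
successes/trials, so normalized counts are produced on a common-library
scale and rounded half-away-from-zero back to integers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import JointCounts

logger = logging.getLogger(__name__)

__all__ = ["NormFactors", "tmm_factors", "normalize_counts", "filter_and_pseudocount"]

MIN_GENES_FOR_TRIM = 10


@dataclass(frozen=True)
class NormFactors:
    """Per-column TMM scaling factors and library sizes.

    Factors are rescaled to geometric mean 1; the effective library size of
    column j is ``lib_sizes[j] * factors[j]``.
    """

    columns: tuple[str, ...]
    factors: np.ndarray
    lib_sizes: np.ndarray
    reference: str

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors

    def __post_init__(self):
        if np.any(self.factors <= 0):
            raise ValueError("all TMM factors must be positive")


def _upper_quartile(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    scaled = counts / lib_sizes
    return np.quantile(scaled, 0.75, axis=0)


def _tmm_pair(
    x: np.ndarray, xr: np.ndarray, n: float, nr: float,
    trim_m: float, trim_a: float,
) -> float:
    """One column's TMM factor against the reference column."""
    ok = (x > 0) & (xr > 0)
    x, xr = x[ok].astype(float), xr[ok].astype(float)
    if x.size < MIN_GENES_FOR_TRIM:
        warnings.warn(
            f"fewer than {MIN_GENES_FOR_TRIM} genes shared with the "
            "reference survive; using factor 1"
        )
        return 1.0
    m = np.log2((x / n) / (xr / nr))
    a = 0.5 * np.log2((x / n) * (xr / nr))
    v = (n - x) / (n * x) + (nr - xr) / (nr * xr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    ng = m.size
    lo_m = np.floor(ng * trim_m) + 1
    hi_m = ng + 1 - lo_m
    lo_a = np.floor(ng * trim_a) + 1
    hi_a = ng + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        warnings.warn("trimming removed all genes; using factor 1")
        return 1.0
    # inverse-variance weights: w = 1/v, so the factor is
    # 2^( sum(M/v) / sum(1/v) ) over the doubly trimmed gene set
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    matrix,
    reference_column: int | str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """TMM scaling factors across the count columns of a matrix.

    Parameters
    ----------
    matrix : JointCounts or DataFrame
        Raw counts, genes in rows.
    reference_column : int, str, optional
        Reference column; defaults to the column whose upper-quartile
        (depth-scaled) count is closest to the mean upper quartile.
    trim_m, trim_a : float
        Two-sided trim fractions on the log-ratio (M) and average
        log-intensity (A) scales.
    """
    counts = matrix.counts if isinstance(matrix, JointCounts) else matrix
    cols = tuple(counts.columns)
    if len(cols) < 2:
        raise ValueError("TMM needs at least two columns")
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if np.any(lib <= 0):
        bad = [c for c, s in zip(cols, lib) if s <= 0]
        raise ValueError(f"column(s) with zero total count: {bad}")

    if reference_column is None:
        uq = _upper_quartile(arr, lib)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    elif isinstance(reference_column, str):
        ref_idx = cols.index(reference_column)
    else:
        ref_idx = int(reference_column)

    factors = np.ones(len(cols))
    for j in range(len(cols)):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            arr[:, j], arr[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        columns=cols, factors=factors, lib_sizes=lib, reference=cols[ref_idx]
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_counts(matrix, factors: NormFactors):
    """Rescale counts to a common effective library and round to integers.

    cell = round( x_gj / (N_j f_j) * mean_j(N_j f_j) ), rounding
    half-away-from-zero, so a column's counts are divided by its effective
    library size and re-expressed on the average effective library.
    Returns the same container type as the input, flagged normalized.
    """
    is_joint = isinstance(matrix, JointCounts)
    counts = matrix.counts if is_joint else matrix
    if tuple(counts.columns) != factors.columns:
        raise ValueError("factors were computed on different columns")
    eff = factors.effective_lib_sizes
    scaled = counts.to_numpy(dtype=float) / eff * eff.mean()
    normed = pd.DataFrame(
        _round_half_away(scaled).astype("int64"),
        index=counts.index,
        columns=counts.columns,
    )
    if is_joint:
        return matrix.with_counts(normed, normalized=True)
    return normed


def filter_and_pseudocount(
    pairs: pd.DataFrame, min_total: int = 20
) -> tuple[pd.DataFrame, pd.Series]:
    """Zero->1 pseudocount, then drop rows whose two-column total is below
    ``min_total``.

    Each zero cell is replaced by 1 (only zeros — so ratios are always
    defined without shifting nonzero counts), after which rows with
    a + b < min_total are removed. Returns (retained rows, boolean
    retained-mask over the input index). Idempotent.
    """
    if pairs.shape[1] != 2:
        raise ValueError("expected exactly two count columns")
    filled = pairs.where(pairs > 0, 1)
    mask = filled.sum(axis=1) >= min_total
    logger.info(
        "filter_and_pseudocount: retained %d of %d rows (total >= %d)",
        int(mask.sum()), len(pairs), min_total,
    )
    return filled[mask], mask
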