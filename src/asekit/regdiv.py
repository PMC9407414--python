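"""Cis/trans regulatory-divergence classification.

For each ortholog pair the parental log2 expression ratio P and the hybrid
log2 allelic ratio H are compared. Because both parental alleles share one
nucleus in the hybrid, allelic imbalance there (H != 0) isolates linked,
allele-local (cis) regulatory divergence, while the trans component is the
remainder T = P - H. Three tests feed the classification:

* a binomial exact test (p0 = 0.5) on the parent pair  -> is P != 0?
* a binomial exact test (p0 = 0.5) on the hybrid pair  -> is H != 0?
* a Fisher exact test on the 2x2 [parent a, b; hybrid a, b] -> is P != H?

With A/B/C the significance indicators of those tests at a single FDR
threshold (default 0.5%), genes fall into seven categories:

=============  ==========================================================
CONSERVED      none significant — no detectable regulatory divergence
CIS            A, B significant, C not: parents differ, hybrid alleles
               differ the same way
TRANS          A, C significant, B not: parents differ but hybrid alleles
               are balanced
CIS_PLUS_TRANS all three significant, H and T the same sign (synergistic)
CIS_X_TRANS    all three significant, H and T opposite signs (antagonistic)
COMPENSATING   B, C significant, A not: allelic imbalance cancelled by an
               opposing trans effect
AMBIGUOUS      any remaining pattern, and sign ties (H = 0 or T = 0 with
               all three significant)
=============  ==========================================================
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import JointCounts, RunConfig
from .normalization import filter_and_pseudocount
from .stats import (
    bh_fdr,
    binom_exact_two_sided,
    chi2_yates_2x2,
    fisher_exact_two_sided,
    log2_ratio,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "CategoryCountTable",
    "compute_pht",
    "classify_gene",
    "run_regdiv",
    "compare_backcrosses",
    "RegulatoryDivergence",
    "RegulatoryDivergenceResults",
]


class Category(str, enum.Enum):
    CIS = "cis"
    TRANS = "trans"
    CIS_PLUS_TRANS = "cis_plus_trans"
    CIS_X_TRANS = "cis_x_trans"
    COMPENSATING = "compensating"
    AMBIGUOUS = "ambiguous"
    CONSERVED = "conserved"

    def __str__(self) -> str:  # keeps TSV output plain
        return self.value


CATEGORY_ORDER = (
    Category.CIS,
    Category.CIS_PLUS_TRANS,
    Category.CIS_X_TRANS,
    Category.COMPENSATING,
    Category.TRANS,
    Category.AMBIGUOUS,
    Category.CONSERVED,
)


def compute_pht(
    parent_pair: tuple[float, float], hybrid_pair: tuple[float, float]
) -> tuple[float, float, float]:
    """P, H and T for one gene from pseudocounted (positive) count pairs.

    P = log2(parent_a / parent_b), H = log2(hybrid_a / hybrid_b),
    T = P - H.
    """
    a_p, b_p = parent_pair
    a_h, b_h = hybrid_pair
    p = log2_ratio(a_p, b_p)
    h = log2_ratio(a_h, b_h)
    return p, h, p - h


def classify_gene(
    q_parent: float,
    q_hybrid: float,
    q_fisher: float,
    h: float,
    t: float,
    alpha: float = 0.005,
) -> Category:
    """Seven-way cis/trans category from the three q-values and the signs
    of H and T (see the module docstring for the rule table)."""
    sig_p = q_parent < alpha
    sig_h = q_hybrid < alpha
    sig_f = q_fisher < alpha
    if not sig_p and not sig_h and not sig_f:
        return Category.CONSERVED
    if sig_p and sig_h and not sig_f:
        return Category.CIS
    if sig_p and not sig_h and sig_f:
        return Category.TRANS
    if sig_p and sig_h and sig_f:
        s = np.sign(h) * np.sign(t)
        if s > 0:
            return Category.CIS_PLUS_TRANS
        if s < 0:
            return Category.CIS_X_TRANS
        return Category.AMBIGUOUS  # sign tie: H == 0 or T == 0
    if not sig_p and sig_h and sig_f:
        return Category.COMPENSATING
    return Category.AMBIGUOUS


@dataclass(frozen=True)
class CategoryCountTable:
    """Per-category gene counts and percentages for one backcross run."""

    counts: dict[Category, int]
    label: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, category: Category) -> float:
        """Percentage of the retained total, printed style (1 decimal)."""
        return round(100.0 * self.counts.get(category, 0) / self.total, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": str(c),
                "count": self.counts.get(c, 0),
                "percent": self.percentage(c),
            }
            for c in CATEGORY_ORDER
        ]
        df = pd.DataFrame(rows).set_index("category")
        df.loc["total"] = [self.total, 100.0]
        df["count"] = df["count"].astype(int)
        return df


def run_regdiv(
    joint: JointCounts, backcross: str, config: RunConfig | None = None
) -> tuple[pd.DataFrame, CategoryCountTable]:
    """Full per-gene classification for one backcross.

    Expects normalized joint counts. Both the parent pair and the chosen
    backcross's allele pair are zero->1 pseudocounted; genes are retained
    when the parent total meets ``config.min_total``. The three tests run
    per retained gene, BH-FDR is applied within each test family, and each
    gene receives exactly one category at ``config.alpha_regdiv``.

    Returns (per-gene records, category count table).
    """
    config = config or RunConfig()
    if not joint.normalized:
        raise ValueError("run_regdiv expects TMM-normalized joint counts")

    parents = joint.parent_pair()
    parents_f, mask = filter_and_pseudocount(parents, config.min_total)
    if parents_f.empty:
        raise ValueError(
            f"no gene passed the parent total >= {config.min_total} filter"
        )
    hybrid = joint.hybrid_pair(backcross).loc[parents_f.index]
    hybrid_f = hybrid.where(hybrid > 0, 1)
    logger.info(
        "run_regdiv[%s]: %d of %d ortholog pairs retained",
        backcross, len(parents_f), len(joint),
    )

    ap = parents_f.iloc[:, 0].to_numpy()
    bp = parents_f.iloc[:, 1].to_numpy()
    ah = hybrid_f.iloc[:, 0].to_numpy()
    bh = hybrid_f.iloc[:, 1].to_numpy()

    p_val = np.log2(ap / bp)
    h_val = np.log2(ah / bh)
    t_val = p_val - h_val

    p_parent = np.array(
        [binom_exact_two_sided(a, a + b).p_value for a, b in zip(ap, bp)]
    )
    p_hybrid = np.array(
        [binom_exact_two_sided(a, a + b).p_value for a, b in zip(ah, bh)]
    )
    p_fisher = np.array(
        [
            fisher_exact_two_sided([[a, b], [c, d]]).p_value
            for a, b, c, d in zip(ap, bp, ah, bh)
        ]
    )
    q_parent = bh_fdr(p_parent)
    q_hybrid = bh_fdr(p_hybrid)
    q_fisher = bh_fdr(p_fisher)

    categories = [
        classify_gene(qp, qh, qf, h, t, config.alpha_regdiv)
        for qp, qh, qf, h, t in zip(q_parent, q_hybrid, q_fisher, h_val, t_val)
    ]
    records = pd.DataFrame(
        {
            "P": p_val,
            "H": h_val,
            "T": t_val,
            "p_parent": p_parent,
            "p_hybrid": p_hybrid,
            "p_fisher": p_fisher,
            "q_parent": q_parent,
            "q_hybrid": q_hybrid,
            "q_fisher": q_fisher,
            "category": [str(c) for c in categories],
        },
        index=parents_f.index,
    )
    counts = {c: 0 for c in CATEGORY_ORDER}
    for c in categories:
        counts[c] += 1
    return records, CategoryCountTable(counts=counts, label=backcross)


def compare_backcrosses(
    t1: CategoryCountTable, t2: CategoryCountTable
) -> pd.DataFrame:
    """Per-category 2x2 Yates chi-square comparison of two category tables.

    For each category the table [[count1, total1 - count1],
    [count2, total2 - count2]] is tested; returns a frame with both counts,
    the chi-square statistic and the two-tailed p-value.
    """
    if t1.total == 0 or t2.total == 0:
        raise ValueError("both category tables must be nonempty")
    rows = []
    for c in CATEGORY_ORDER:
        c1, c2 = t1.counts.get(c, 0), t2.counts.get(c, 0)
        res = chi2_yates_2x2(
            [[c1, t1.total - c1], [c2, t2.total - c2]]
        )
        rows.append(
            {
                "category": str(c),
                "count_1": c1,
                "count_2": c2,
                "chi2_yates": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("category")


class RegulatoryDivergence:
    """Cis/trans regulatory-divergence model for one backcross.

    Parameters
    ----------
    joint : JointCounts
        TMM-normalized ortholog-paired counts (see
        :func:`asekit.normalization.normalize_counts`).
    backcross : str
        Which backcross's allele pair estimates H.
    config : RunConfig, optional
        Thresholds; defaults to the published analysis settings.

    Examples
    --------
    >>> model = RegulatoryDivergence(joint, "BC2")   # doctest: +SKIP
    >>> res = model.fit()                            # doctest: +SKIP
    >>> print(res.summary())                         # doctest: +SKIP
    """

    def __init__(
        self, joint: JointCounts, backcross: str, config: RunConfig | None = None
    ):
        self.joint = joint
        self.backcross = backcross
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        backcross: str,
        config: RunConfig | None = None,
        normalized: bool = True,
    ) -> "RegulatoryDivergence":
        """Build directly from a frame with columns parent_A, parent_B,
        ``{backcross}_A`` and ``{backcross}_B`` (gene ids in the index)."""
        df = data.copy()
        df.insert(0, "gene_a", df.index.astype(str))
        df.insert(1, "gene_b", df.index.astype(str))
        joint = JointCounts(
            data=df, backcrosses=(backcross,), normalized=normalized
        )
        return cls(joint, backcross, config)

    def fit(self) -> "RegulatoryDivergenceResults":
        records, table = run_regdiv(self.joint, self.backcross, self.config)
        return RegulatoryDivergenceResults(self, records, table)


@dataclass
class RegulatoryDivergenceResults:
    """Fitted per-gene P/H/T estimates, q-values and categories."""

    model: RegulatoryDivergence
    records: pd.DataFrame
    category_table: CategoryCountTable

    @property
    def n_genes(self) -> int:
        return len(self.records)

    def compare(self, other: "RegulatoryDivergenceResults") -> pd.DataFrame:
        return compare_backcrosses(self.category_table, other.category_table)

    def summary(self) -> str:
        lines = [
            "Regulatory divergence classification",
            "====================================",
            f"backcross:         {self.model.backcross}",
            f"genes retained:    {self.n_genes}",
            f"FDR threshold:     {self.model.config.alpha_regdiv}",
            "",
            self.category_table.to_frame().to_string(),
        ]
        return "\n".join(lines)
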