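"""Per-backcross allelic-imbalance calling, the genome–transcriptome
incongruence z-test, and cross-backcross joint/switching classification.

A backcross hybrid carries a known expected fraction of the recurrent
parent's genome (87.5% after two backcrosses, 93.75% after three). Among
the genes whose two alleles are asymmetrically expressed, the fraction
preferring the recurrent-parent (A) allele can be compared with that
genomic fraction: a significant disproportion is genome–transcriptome
incongruence, quantified by a two-proportion z statistic.

When the same genes are called in both backcrosses, each gene falls into
one of five joint categories; genes significant in both but with opposite
allelic direction exhibit preferential expression switching.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import JointCounts, RunConfig
from .normalization import filter_and_pseudocount, normalize_counts, tmm_factors
from .stats import TestResult, bh_fdr, binom_exact_two_sided, two_proportion_z

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "JointCategory",
    "SwitchDirection",
    "IncongruenceResult",
    "call_ase",
    "preference_counts",
    "incongruence_test",
    "cross_classify",
    "AllelicImbalance",
    "AllelicImbalanceResults",
    "CrossBackcross",
    "CrossBackcrossResults",
]


class Direction(str, enum.Enum):
    A_PREFERRED = "A"
    B_PREFERRED = "B"
    NONE = "none"

    def __str__(self) -> str:
        return self.value


class JointCategory(str, enum.Enum):
    CONSERVED_ASYMMETRIC = "conserved_asymmetric"
    CONSERVED_SYMMETRIC = "conserved_symmetric"
    BC2_SPECIFIC = "first_specific"
    BC3_SPECIFIC = "second_specific"
    SWITCHING = "switching"

    def __str__(self) -> str:
        return self.value


class SwitchDirection(str, enum.Enum):
    A_TO_B = "A_to_B"
    B_TO_A = "B_to_A"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class IncongruenceResult:
    """Observed vs expected allele-preference proportions for one backcross."""

    backcross: str
    expected_prop: float
    observed_prop: float
    n_genome: int
    n_ase: int
    z: float
    p_value: float


def call_ase(
    hybrid_pairs: pd.DataFrame,
    config: RunConfig | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Allelic-imbalance calls for one backcross's (A, B) allele counts.

    Zero cells are pseudocounted to 1, pairs with total below
    ``config.min_total`` are dropped, each retained gene gets a binomial
    exact test (p0 = 0.5) on the A count out of the pair total, and BH-FDR
    is applied across the retained genes. A gene is directional only under
    the dual threshold: q < alpha AND |log2FC| >= config.lfc_threshold; the
    direction follows the sign of log2FC (A when positive).

    Returns a frame with columns log2fc, p_value, q_value, direction.
    """
    config = config or RunConfig()
    alpha = config.alpha_ase if alpha is None else alpha
    if hybrid_pairs.empty:
        raise ValueError("no allele-count pairs supplied")
    pairs, _ = filter_and_pseudocount(hybrid_pairs, config.min_total)
    if pairs.empty:
        raise ValueError(
            f"no gene passed the allele total >= {config.min_total} filter"
        )
    a = pairs.iloc[:, 0].to_numpy()
    b = pairs.iloc[:, 1].to_numpy()
    lfc = np.log2(a / b)
    p = np.array([binom_exact_two_sided(x, x + y).p_value for x, y in zip(a, b)])
    q = bh_fdr(p)
    significant = (q < alpha) & (np.abs(lfc) >= config.lfc_threshold)
    direction = np.where(
        significant,
        np.where(lfc > 0, Direction.A_PREFERRED.value, Direction.B_PREFERRED.value),
        Direction.NONE.value,
    )
    return pd.DataFrame(
        {"log2fc": lfc, "p_value": p, "q_value": q, "direction": direction},
        index=pairs.index,
    )


def preference_counts(calls: pd.DataFrame) -> tuple[int, int, int]:
    """(A-preferred, B-preferred, total significant) from an ASE call table."""
    n_a = int((calls["direction"] == Direction.A_PREFERRED.value).sum())
    n_b = int((calls["direction"] == Direction.B_PREFERRED.value).sum())
    return n_a, n_b, n_a + n_b


def incongruence_test(
    n_a: int,
    n_sig: int,
    genomic_prop: float,
    n_genome: int,
    backcross: str = "",
) -> IncongruenceResult:
    """Genome–transcriptome incongruence z-test for one backcross.

    Compares the expected recurrent-genome fraction (over a gene universe
    of ``n_genome``) with the observed fraction ``n_a / n_sig`` of
    A-preferred genes among the significantly imbalanced ones.
    """
    if n_sig < 1:
        raise ValueError("need at least one significantly imbalanced gene")
    res: TestResult = two_proportion_z(genomic_prop, n_genome, n_a, n_sig)
    return IncongruenceResult(
        backcross=backcross,
        expected_prop=genomic_prop,
        observed_prop=n_a / n_sig,
        n_genome=n_genome,
        n_ase=n_sig,
        z=res.statistic,
        p_value=res.p_value,
    )


def cross_classify(
    calls_first: pd.DataFrame,
    calls_second: pd.DataFrame,
) -> pd.DataFrame:
    """Joint five-way classification of genes called in two backcrosses.

    Inputs are ASE call tables (from :func:`call_ase`, run at the joint
    stage's stricter threshold) sharing a gene index; the classification is
    computed on the union of their indices — a gene absent from one table
    (it failed that backcross's count filter) counts as not significant
    there, so gene sets are never silently intersected.

    With S1/S2 the significance of a gene in the first/second backcross:
    CONSERVED_SYMMETRIC when neither is significant; *_SPECIFIC when only
    one is; and when both are, CONSERVED_ASYMMETRIC if the log2FC signs
    agree, otherwise SWITCHING with direction A_to_B (preferred A first,
    then B) or B_to_A.
    """
    idx = calls_first.index.union(calls_second.index)
    if idx.empty:
        raise ValueError("joined gene set is empty")
    c1 = calls_first.reindex(idx)
    c2 = calls_second.reindex(idx)
    s1 = (c1["direction"].fillna(Direction.NONE.value) != Direction.NONE.value)
    s2 = (c2["direction"].fillna(Direction.NONE.value) != Direction.NONE.value)
    h1 = c1["log2fc"]
    h2 = c2["log2fc"]

    category = np.where(
        ~s1 & ~s2,
        JointCategory.CONSERVED_SYMMETRIC.value,
        np.where(
            s1 & ~s2,
            JointCategory.BC2_SPECIFIC.value,
            np.where(
                ~s1 & s2,
                JointCategory.BC3_SPECIFIC.value,
                np.where(
                    np.sign(h1) == np.sign(h2),
                    JointCategory.CONSERVED_ASYMMETRIC.value,
                    JointCategory.SWITCHING.value,
                ),
            ),
        ),
    )
    switch = np.where(
        (category == JointCategory.SWITCHING.value) & (h1 > 0),
        SwitchDirection.A_TO_B.value,
        np.where(
            (category == JointCategory.SWITCHING.value) & (h1 < 0),
            SwitchDirection.B_TO_A.value,
            "",
        ),
    )
    return pd.DataFrame(
        {
            "log2fc_1": h1,
            "log2fc_2": h2,
            "q_value_1": c1["q_value"],
            "q_value_2": c2["q_value"],
            "joint_category": category,
            "switch_direction": switch,
        },
        index=idx,
    )


def _joint_summary(cross: pd.DataFrame) -> dict:
    counts = {
        str(c): int((cross["joint_category"] == c.value).sum())
        for c in JointCategory
    }
    split = {
        str(d): int((cross["switch_direction"] == d.value).sum())
        for d in SwitchDirection
    }
    return {"joint_counts": counts, "switching_split": split, "total": len(cross)}


class AllelicImbalance:
    """Allelic-imbalance model for one backcross's allele-specific counts.

    Parameters
    ----------
    joint : JointCounts
        Normalized joint counts (only the chosen backcross's allele columns
        are used).
    backcross : str
        Backcross label; also selects ``config.genomic_prop`` /
        ``config.n_genome`` for the incongruence test.
    config : RunConfig, optional
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
        pairs: pd.DataFrame,
        backcross: str,
        config: RunConfig | None = None,
    ) -> "AllelicImbalance":
        df = pairs.copy()
        df.columns = [f"{backcross}_A", f"{backcross}_B"]
        df.insert(0, "gene_a", df.index.astype(str))
        df.insert(1, "gene_b", df.index.astype(str))
        df["parent_A"] = 0
        df["parent_B"] = 0
        joint = JointCounts(data=df, backcrosses=(backcross,), normalized=True)
        return cls(joint, backcross, config)

    def fit(self) -> "AllelicImbalanceResults":
        if not self.joint.normalized:
            raise ValueError("AllelicImbalance expects normalized counts")
        calls = call_ase(self.joint.hybrid_pair(self.backcross), self.config)
        n_a, n_b, n_sig = preference_counts(calls)
        incong = None
        gp = self.config.genomic_prop.get(self.backcross)
        ng = self.config.n_genome.get(self.backcross)
        if gp is not None and ng is not None and n_sig >= 1:
            incong = incongruence_test(n_a, n_sig, gp, ng, self.backcross)
        return AllelicImbalanceResults(self, calls, (n_a, n_b, n_sig), incong)


@dataclass
class AllelicImbalanceResults:
    """Fitted ASE calls, preference tallies and the incongruence test."""

    model: AllelicImbalance
    calls: pd.DataFrame
    preferences: tuple[int, int, int]
    incongruence: IncongruenceResult | None

    def summary(self) -> str:
        n_a, n_b, n_sig = self.preferences
        lines = [
            "Allelic imbalance",
            "=================",
            f"backcross:             {self.model.backcross}",
            f"genes tested:          {len(self.calls)}",
            f"significant (dual thr):{n_sig}",
            f"  A-preferred:         {n_a}",
            f"  B-preferred:         {n_b}",
        ]
        if self.incongruence is not None:
            i = self.incongruence
            lines += [
                "",
                "Genome-transcriptome incongruence",
                f"  expected A fraction: {i.expected_prop:.4f} (N={i.n_genome})",
                f"  observed A fraction: {i.observed_prop:.4f} (n={i.n_ase})",
                f"  z = {i.z:.2f}, two-tailed p = {i.p_value:.3g}",
            ]
        return "\n".join(lines)


class CrossBackcross:
    """Joint/switching model across two backcrosses.

    The two backcrosses' allele columns are concatenated into one matrix
    and TMM re-normalized jointly (backcross columns only); genes with a
    pseudocounted allele total of at least ``config.min_total`` in either
    backcross are retained, per-backcross binomial calls run at the
    stricter joint threshold (``config.alpha_joint``, default FDR < 0.5%),
    and each gene is classified into the five joint categories.
    """

    def __init__(
        self,
        joint: JointCounts,
        backcrosses: tuple[str, str] | None = None,
        config: RunConfig | None = None,
        renormalize: bool = True,
    ):
        self.joint = joint
        self.backcrosses = backcrosses or tuple(joint.backcrosses[:2])
        if len(self.backcrosses) != 2:
            raise ValueError("CrossBackcross needs exactly two backcrosses")
        self.config = config or RunConfig()
        self.renormalize = renormalize

    def fit(self) -> "CrossBackcrossResults":
        bc1, bc2 = self.backcrosses
        cols = [f"{bc1}_A", f"{bc1}_B", f"{bc2}_A", f"{bc2}_B"]
        raw = self.joint.data[cols]
        if self.renormalize:
            factors = tmm_factors(raw)
            counts = normalize_counts(raw, factors)
        else:
            counts = raw
        pc = counts.where(counts > 0, 1)
        tot1 = pc[[f"{bc1}_A", f"{bc1}_B"]].sum(axis=1)
        tot2 = pc[[f"{bc2}_A", f"{bc2}_B"]].sum(axis=1)
        keep = (tot1 >= self.config.min_total) | (tot2 >= self.config.min_total)
        if not keep.any():
            raise ValueError("no gene passed the either-backcross total filter")
        logger.info(
            "cross-backcross stage: %d of %d genes retained (total >= %d in "
            "either backcross)", int(keep.sum()), len(counts), self.config.min_total,
        )
        pc = pc[keep]
        calls = {}
        for bc in (bc1, bc2):
            calls[bc] = call_ase(
                pc[[f"{bc}_A", f"{bc}_B"]],
                self.config,
                alpha=self.config.alpha_joint,
            )
        cross = cross_classify(calls[bc1], calls[bc2])
        return CrossBackcrossResults(self, calls, cross, _joint_summary(cross))


@dataclass
class CrossBackcrossResults:
    """Per-gene joint categories plus the five-way and switching tallies."""

    model: CrossBackcross
    calls: dict[str, pd.DataFrame]
    cross: pd.DataFrame
    counts: dict

    def scatter_data(self) -> pd.DataFrame:
        """Plot-ready frame of per-gene log2 ratios in each backcross with
        the joint category (the input behind an H1-vs-H2 scatter)."""
        return self.cross[["log2fc_1", "log2fc_2", "joint_category"]].dropna(
            subset=["log2fc_1", "log2fc_2"]
        )

    def summary(self) -> str:
        bc1, bc2 = self.model.backcrosses
        jc = self.counts["joint_counts"]
        split = self.counts["switching_split"]
        lines = [
            "Cross-backcross allelic imbalance",
            "=================================",
            f"backcrosses:        {bc1}, {bc2}",
            f"genes classified:   {self.counts['total']}",
            f"FDR threshold:      {self.model.config.alpha_joint}",
            "",
        ]
        lines += [f"  {k:<22}{v}" for k, v in jc.items()]
        lines += [
            "",
            f"switching A->B: {split[str(SwitchDirection.A_TO_B)]}, "
            f"B->A: {split[str(SwitchDirection.B_TO_A)]}",
        ]
        return "\n".join(lines)
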