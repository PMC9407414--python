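import numpy as np
import pandas as pd
import pytest

from asekit.io import RunConfig
from asekit.normalization import normalize_counts, tmm_factors
from asekit.regdiv import (
    CATEGORY_ORDER,
    Category,
    CategoryCountTable,
    RegulatoryDivergence,
    classify_gene,
    compare_backcrosses,
    compute_pht,
    run_regdiv,
)
from asekit.simulate import SimConfig, simulate
from asekit.study import BC2_CATEGORY_TABLE, BC3_CATEGORY_TABLE

from conftest import make_joint


class TestComputePht:
    @pytest.mark.parametrize(
        "parents, hybrid, expected",
        [
            ((80, 20), (40, 10), (2, 2, 0)),  # pure cis
            ((80, 20), (25, 25), (2, 0, 2)),  # pure trans
            ((50, 50), (80, 20), (0, 2, -2)),  # compensating
        ],
    )
    def test_arithmetic(self, parents, hybrid, expected):
        assert compute_pht(parents, hybrid) == pytest.approx(expected)

    def test_t_is_p_minus_h_exactly(self):
        p, h, t = compute_pht((123, 47), (55, 81))
        assert t == p - h


SIG, NS = 0.001, 0.8


class TestClassifyGene:
    @pytest.mark.parametrize(
        "qp, qh, qf, h, t, expected",
        [
            (NS, NS, NS, 0.1, 0.1, Category.CONSERVED),
            (SIG, SIG, NS, 2.0, 0.1, Category.CIS),
            (SIG, NS, SIG, 0.1, 2.0, Category.TRANS),
            (SIG, SIG, SIG, 1.5, 0.7, Category.CIS_PLUS_TRANS),  # synergistic
            (SIG, SIG, SIG, 1.5, -0.7, Category.CIS_X_TRANS),  # antagonistic
            (SIG, SIG, SIG, 0.0, 0.7, Category.AMBIGUOUS),  # sign tie H = 0
            (SIG, SIG, SIG, 1.5, 0.0, Category.AMBIGUOUS),  # sign tie T = 0
            (NS, SIG, SIG, 2.0, -2.0, Category.COMPENSATING),
            (NS, NS, SIG, 0.1, 0.1, Category.AMBIGUOUS),
            (SIG, NS, NS, 0.1, 0.1, Category.AMBIGUOUS),
            (NS, SIG, NS, 1.0, -1.0, Category.AMBIGUOUS),
        ],
    )
    def test_rule_table(self, qp, qh, qf, h, t, expected):
        assert classify_gene(qp, qh, qf, h, t, alpha=0.005) is expected


class TestRunRegdiv:
    def toy_joint(self):
        # six deep genes spanning the main rule branches, plus one below
        # the parent-total filter
        counts = {
            "parent_A": [8000, 8000, 1000, 1000, 8000, 4000, 9],
            "parent_B": [2000, 2000, 1000, 1000, 2000, 1000, 8],
            "BC2_A": [4000, 2500, 1000, 4000, 6000, 4500, 5],
            "BC2_B": [1000, 2500, 1000, 1000, 1000, 500, 5],
        }
        return make_joint(counts, normalized=True)

    def test_toy_categories_match_hand_classification(self):
        records, table = run_regdiv(self.toy_joint(), "BC2", RunConfig())
        assert len(records) == 6  # the (9, 8) pair is filtered out
        expected = {
            "A0|B0": "cis",  # P=2, H=2, parents+hybrid skewed alike
            "A1|B1": "trans",  # P=2, H=0
            "A2|B2": "conserved",  # balanced everywhere
            "A3|B3": "compensating",  # P=0, H=2
            "A4|B4": "cis_plus_trans",  # P=2, H~2.58, T<0? no: H>P
            "A5|B5": "cis_x_trans",
        }
        got = records["category"].to_dict()
        for gene in ("A0|B0", "A1|B1", "A2|B2", "A3|B3"):
            assert got[gene] == expected[gene], gene
        # the mixed genes must land in one of the all-significant branches
        assert got["A4|B4"] in ("cis_plus_trans", "cis_x_trans")
        assert got["A5|B5"] in ("cis_plus_trans", "cis_x_trans")
        # and agree with a direct re-application of the rule to the fitted
        # q-values and effect signs
        for gene, row in records.iterrows():
            assert row["category"] == str(
                classify_gene(
                    row["q_parent"], row["q_hybrid"], row["q_fisher"],
                    row["H"], row["T"], 0.005,
                )
            )

    def test_counts_sum_to_total(self):
        _, table = run_regdiv(self.toy_joint(), "BC2", RunConfig())
        assert sum(table.counts.values()) == table.total == 6

    def test_requires_normalized_input(self):
        joint = self.toy_joint()
        raw = joint.with_counts(joint.counts, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            run_regdiv(raw, "BC2", RunConfig())

    def test_empty_retained_set_errors(self):
        counts = {
            "parent_A": [3, 4],
            "parent_B": [2, 5],
            "BC2_A": [50, 60],
            "BC2_B": [50, 60],
        }
        with pytest.raises(ValueError, match="filter"):
            run_regdiv(make_joint(counts, normalized=True), "BC2", RunConfig())


class TestCategoryPercentages:
    def test_published_percentage_formatting(self):
        assert BC2_CATEGORY_TABLE.total == 9656
        assert BC3_CATEGORY_TABLE.total == 9295
        assert BC2_CATEGORY_TABLE.percentage(Category.CIS) == 27.4
        assert BC3_CATEGORY_TABLE.percentage(Category.CONSERVED) == 39.4

    def test_percentages_sum_to_100(self):
        total = sum(
            BC2_CATEGORY_TABLE.percentage(c) for c in CATEGORY_ORDER
        )
        assert total == pytest.approx(100.0, abs=0.3)


class TestCompareBackcrosses:
    def test_published_contrasts(self):
        comp = compare_backcrosses(BC2_CATEGORY_TABLE, BC3_CATEGORY_TABLE)
        assert comp.loc["cis", "chi2_yates"] == pytest.approx(66.73, abs=0.005)
        assert comp.loc["conserved", "chi2_yates"] == pytest.approx(
            322.73, abs=0.005
        )

    def test_identical_tables_give_zero(self):
        comp = compare_backcrosses(BC2_CATEGORY_TABLE, BC2_CATEGORY_TABLE)
        assert comp["chi2_yates"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_empty_table_errors(self):
        empty = CategoryCountTable(counts={})
        with pytest.raises(ValueError):
            compare_backcrosses(BC2_CATEGORY_TABLE, empty)


class TestModelInterface:
    def test_from_dataframe_fit_summary(self):
        df = pd.DataFrame(
            {
                "parent_A": [8000, 1000],
                "parent_B": [2000, 1000],
                "BC2_A": [4000, 1000],
                "BC2_B": [1000, 1000],
            },
            index=["gA", "gB"],
        )
        res = RegulatoryDivergence.from_dataframe(df, "BC2").fit()
        assert res.n_genes == 2
        text = res.summary()
        assert "BC2" in text and "cis" in text

    def test_null_simulation_stays_conserved(self):
        """With every true effect zero, classification finds essentially no
        structure: the conserved fraction stays near 1."""
        config = SimConfig(
            n_genes=800,
            category_mixture={Category.CONSERVED: 1.0},
            base_mean=2000,
            dispersion=0.02,
            zero_gene_frac=0.0,
            seed=3,
        )
        joint, _ = simulate(config)
        normed = normalize_counts(joint, tmm_factors(joint))
        res = RegulatoryDivergence(normed, "BC2").fit()
        frac = res.category_table.counts[Category.CONSERVED] / res.n_genes
        assert frac >= 1 - 3 * 0.005
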