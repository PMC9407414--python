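import numpy as np
import pandas as pd
import pytest

from asekit.imbalance import (
    AllelicImbalance,
    CrossBackcross,
    Direction,
    JointCategory,
    call_ase,
    cross_classify,
    incongruence_test,
    preference_counts,
)
from asekit.io import RunConfig
from asekit.simulate import SimConfig, simulate
from asekit.study import INCONGRUENCE_INPUTS

from conftest import make_joint


def pairs_frame(rows, index=None):
    index = index or [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=["A", "B"], index=index)


class TestCallAse:
    def test_direction_rules(self):
        calls = call_ase(
            pairs_frame([(100, 100), (400, 100), (300, 200), (100, 400)]),
            RunConfig(),
        )
        assert calls.loc["g0", "direction"] == "none"  # balanced
        assert calls.loc["g1", "direction"] == "A"  # 4-fold, q tiny
        # |log2fc| = 0.585 < 1: biological threshold blocks the call even
        # though the binomial q-value is significant
        assert calls.loc["g2", "q_value"] < 0.05
        assert calls.loc["g2", "direction"] == "none"
        assert calls.loc["g3", "direction"] == "B"

    def test_direction_iff_dual_threshold(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 400, 300)
        b = rng.integers(0, 400, 300)
        calls = call_ase(pairs_frame(list(zip(a, b))), RunConfig())
        sig = (calls["q_value"] < 0.05) & (calls["log2fc"].abs() >= 1.0)
        assert ((calls["direction"] != "none") == sig).all()
        pos = calls["direction"] == "A"
        assert (calls.loc[pos, "log2fc"] > 0).all()

    def test_filter_applied_after_pseudocount(self):
        calls = call_ase(pairs_frame([(0, 25), (12, 7)]), RunConfig())
        assert list(calls.index) == ["g0"]  # (1+25)=26 kept, (12+7)=19 dropped

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            call_ase(pairs_frame([]), RunConfig())


class TestPreferenceCounts:
    def test_tally(self):
        calls = pd.DataFrame({"direction": ["A", "B", "B", "none"]})
        assert preference_counts(calls) == (1, 2, 3)

    def test_all_none(self):
        calls = pd.DataFrame({"direction": ["none"] * 4})
        assert preference_counts(calls) == (0, 0, 0)

    def test_null_simulation_significant_fraction_small(self):
        """Deep balanced data with no true effects: the dual-threshold
        significant fraction stays below the FDR level."""
        rng = np.random.default_rng(9)
        totals = rng.integers(1000, 5000, 500)
        a = rng.binomial(totals, 0.5)
        calls = call_ase(
            pairs_frame(list(zip(a, totals - a))), RunConfig()
        )
        _, _, n_sig = preference_counts(calls)
        assert n_sig / len(calls) <= 0.05


class TestIncongruence:
    @pytest.mark.parametrize(
        "bc, printed_z, tol",
        [("BC2", 70.4, 0.05), ("BC3", 88.30, 0.005)],
    )
    def test_published_inputs_reproduce_z(self, bc, printed_z, tol):
        inp = INCONGRUENCE_INPUTS[bc]
        res = incongruence_test(
            inp["n_a"], inp["n_sig"], inp["genomic_prop"], inp["n_genome"], bc
        )
        assert res.z == pytest.approx(printed_z, abs=tol)
        assert res.p_value < 1e-4
        assert res.observed_prop == pytest.approx(inp["n_a"] / inp["n_sig"])

    def test_matching_proportion_gives_zero(self):
        res = incongruence_test(7, 8, 0.875, 1000, "BC2")
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_when_preferences_match_genome(self):
        """When the fraction of genes truly preferring the recurrent allele
        equals the genomic fraction, |z| stays small across replicates."""
        ok = 0
        n_reps = 10
        for rep in range(n_reps):
            config = SimConfig(
                n_genes=600,
                category_mixture={"cis": 1.0},
                effect_low=2.0,
                effect_high=3.0,
                base_mean=3000,
                dispersion=0.02,
                prob_a_up=0.875,
                zero_gene_frac=0.0,
                backcrosses=("BC2",),
                seed=100 + rep,
            )
            joint, _ = simulate(config)
            calls = call_ase(joint.hybrid_pair("BC2"), RunConfig())
            n_a, _, n_sig = preference_counts(calls)
            res = incongruence_test(n_a, n_sig, 0.875, 600, "BC2")
            if abs(res.z) < 4:
                ok += 1
        assert ok >= int(0.95 * n_reps)


def calls_from(spec):
    """spec: list of (gene, log2fc, significant)."""
    rows = {
        g: {
            "log2fc": h,
            "p_value": 0.0,
            "q_value": 0.0001 if sig else 0.9,
            "direction": ("A" if h > 0 else "B") if sig else "none",
        }
        for g, h, sig in spec
    }
    return pd.DataFrame.from_dict(rows, orient="index")


class TestCrossClassify:
    def test_definitional_cases(self):
        first = calls_from(
            [("g1", 2.0, True), ("g2", -2.0, True), ("g3", 1.5, True),
             ("g4", 0.2, False), ("g5", 0.1, False)]
        )
        second = calls_from(
            [("g1", 1.5, True), ("g2", 2.0, True), ("g3", 0.3, False),
             ("g4", -1.8, True), ("g5", 0.0, False)]
        )
        cross = cross_classify(first, second)
        cats = cross["joint_category"]
        assert cats["g1"] == str(JointCategory.CONSERVED_ASYMMETRIC)
        assert cats["g2"] == str(JointCategory.SWITCHING)
        assert cross.loc["g2", "switch_direction"] == "B_to_A"
        assert cats["g3"] == str(JointCategory.BC2_SPECIFIC)
        assert cats["g4"] == str(JointCategory.BC3_SPECIFIC)
        assert cats["g5"] == str(JointCategory.CONSERVED_SYMMETRIC)

    def test_switching_direction_semantics(self):
        """B-preferred first then A-preferred is B_to_A; the reverse is
        A_to_B."""
        first = calls_from([("x", -2.0, True), ("y", 2.0, True)])
        second = calls_from([("x", 2.0, True), ("y", -2.0, True)])
        cross = cross_classify(first, second)
        assert cross.loc["x", "switch_direction"] == "B_to_A"
        assert cross.loc["y", "switch_direction"] == "A_to_B"

    def test_union_not_intersection(self):
        first = calls_from([("only1", 2.0, True)])
        second = calls_from([("only2", -2.0, True)])
        cross = cross_classify(first, second)
        assert set(cross.index) == {"only1", "only2"}
        assert (
            cross.loc["only1", "joint_category"]
            == str(JointCategory.BC2_SPECIFIC)
        )

    def test_empty_join_errors(self):
        empty = calls_from([])
        with pytest.raises(ValueError):
            cross_classify(empty, empty)


class TestModels:
    def simulated_normed(self):
        config = SimConfig(n_genes=500, base_mean=2000, dispersion=0.02, seed=17)
        joint, truth = simulate(config)
        return joint, truth

    def test_allelic_imbalance_fit(self):
        joint, _ = self.simulated_normed()
        from asekit.normalization import normalize_counts, tmm_factors

        normed = normalize_counts(joint, tmm_factors(joint))
        res = AllelicImbalance(normed, "BC2").fit()
        n_a, n_b, n_sig = res.preferences
        assert n_a + n_b == n_sig
        assert res.incongruence is not None
        assert "incongruence" in res.summary().lower()

    def test_cross_backcross_partition(self):
        joint, _ = self.simulated_normed()
        res = CrossBackcross(joint).fit()
        jc = res.counts["joint_counts"]
        assert sum(jc.values()) == res.counts["total"] == len(res.cross)
        split = res.counts["switching_split"]
        assert sum(split.values()) == jc[str(JointCategory.SWITCHING)]
        scatter = res.scatter_data()
        assert set(scatter.columns) == {"log2fc_1", "log2fc_2", "joint_category"}
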