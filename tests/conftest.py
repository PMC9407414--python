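import numpy as np
import pandas as pd
import pytest

from asekit.io import JointCounts
from asekit.normalization import normalize_counts, tmm_factors
from asekit.regdiv import RegulatoryDivergence
from asekit.simulate import SimConfig, simulate


def make_joint(counts: dict, backcrosses=("BC2",), normalized=False) -> JointCounts:
    """Build a JointCounts from a dict of column -> list of ints."""
    n = len(next(iter(counts.values())))
    data = pd.DataFrame(
        {
            "gene_a": [f"A{i}" for i in range(n)],
            "gene_b": [f"B{i}" for i in range(n)],
            **counts,
        }
    )
    data.index = pd.Index(data["gene_a"] + "|" + data["gene_b"], name="pair_id")
    return JointCounts(data=data, backcrosses=tuple(backcrosses), normalized=normalized)


@pytest.fixture(scope="session")
def deep_recovery_run():
    """One deep, seed-fixed simulation with large effects, pushed through
    normalization and the cis/trans classifier; reused by recovery tests."""
    config = SimConfig(
        n_genes=2000,
        base_mean=5000,
        dispersion=0.02,
        effect_low=2.0,
        effect_high=3.0,
        seed=20260930,
    )
    joint, truth = simulate(config)
    normed = normalize_counts(joint, tmm_factors(joint))
    results = RegulatoryDivergence(normed, "BC2").fit()
    merged = truth.rename(columns={"category": "category_true"}).join(
        results.records
    )
    return config, truth, results, merged


def recovery_rate(merged: pd.DataFrame, category: str) -> float:
    """Fraction of true-<category> genes assigned that category (genes lost
    to the count filter count as failures)."""
    truth_idx = merged.index[merged["category_true"] == category]
    if len(truth_idx) == 0:
        return float("nan")
    assigned = merged.loc[truth_idx, "category"]
    return float((assigned == category).sum() / len(truth_idx))
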