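"""Synthetic ortholog-paired count data with known cis/trans architecture.

The generator emulates the joint count matrix the analysis consumes: one
parental library per genotype and, per backcross, one pair of
genotype-specific allele counts — with per-gene cis (c) and trans (t)
log2 effects, overdispersed (gamma-Poisson) count noise, unequal library
depths and a fraction of near-silent genes, plus a truth table for
recovery testing.

Generative model per gene (base mean mu, effects split symmetrically so
total expression is effect-independent):

    E[parent A]   = mu * 2^((c + t) / 2)
    E[parent B]   = mu * 2^(-(c + t) / 2)
    E[hybrid A]   = mu * 2^( c / 2) * allele_fraction * 2
    E[hybrid B]   = mu * 2^(-c / 2) * (1 - allele_fraction) * 2

so the expected parental log2 ratio is c + t (= P) and the expected hybrid
allelic log2 ratio is c (= H) when allele fractions are balanced, matching
the estimator T = P - H. Counts are negative binomial with variance
mu + dispersion * mu^2 (Poisson when dispersion = 0), scaled per column by
``depth_factors``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import JointCounts
from .regdiv import Category

__all__ = ["SimConfig", "simulate", "make_switching_scenario"]

# observed architecture of an abaca x banana backcross transcriptome
DEFAULT_MIXTURE: dict[Category, float] = {
    Category.CIS: 0.274,
    Category.CIS_PLUS_TRANS: 0.037,
    Category.CIS_X_TRANS: 0.050,
    Category.COMPENSATING: 0.046,
    Category.TRANS: 0.017,
    Category.AMBIGUOUS: 0.305,
    Category.CONSERVED: 0.271,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    Attributes
    ----------
    n_genes : int
        Number of ortholog pairs.
    category_mixture : mapping
        Proportions over the seven regulatory categories (must sum to 1).
    effect_low, effect_high : float
        Nonzero cis/trans effect magnitudes are drawn uniformly from this
        log2 range (default 1–3, i.e. 2- to 8-fold).
    base_mean : float
        Median per-gene expression scale; per-gene means are lognormal
        around it (sigma ``base_sigma``).
    base_sigma : float
        Lognormal spread of per-gene base means, in natural-log units.
    dispersion : float
        Negative-binomial overdispersion (variance mu + dispersion mu^2);
        0 gives Poisson noise.
    depth_factors : mapping
        Per-column library-depth multipliers (missing columns default 1).
    allele_fraction : float or mapping
        Expected A-allele mapping fraction per backcross (0.5 = balanced
        allele capture).
    prob_a_up : float
        Probability that a nonzero cis effect favours allele A; setting it
        to a backcross's genomic fraction makes the fraction of A-preferred
        genes match that fraction in expectation.
    zero_gene_frac : float
        Fraction of genes made near-silent (base mean ~1) to emulate
        zero-count rows.
    backcrosses : sequence of str
        Backcross labels to generate allele pairs for.
    seed : int
        Generator seed; runs are fully reproducible from it.
    """

    n_genes: int = 2000
    category_mixture: Mapping[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    effect_low: float = 1.0
    effect_high: float = 3.0
    base_mean: float = 1000.0
    base_sigma: float = 0.6
    dispersion: float = 0.05
    depth_factors: Mapping[str, float] = field(default_factory=dict)
    allele_fraction: float | Mapping[str, float] = 0.5
    prob_a_up: float = 0.5
    zero_gene_frac: float = 0.02
    backcrosses: Sequence[str] = ("BC2", "BC3")
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        total = sum(self.category_mixture.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"category mixture must sum to 1, got {total}")
        if any(v < 0 for v in self.category_mixture.values()):
            raise ValueError("mixture proportions must be non-negative")

    def fraction_for(self, backcross: str) -> float:
        if isinstance(self.allele_fraction, Mapping):
            return self.allele_fraction.get(backcross, 0.5)
        return float(self.allele_fraction)


def _draw_effects(config: SimConfig, rng: np.random.Generator):
    """Per-gene true category and (c, t) effects honouring the category
    invariants: CONSERVED c = t = 0; CIS t = 0; TRANS c = 0;
    COMPENSATING c = -t; CIS_PLUS_TRANS same signs; CIS_X_TRANS opposite
    signs with |c| != |t|; AMBIGUOUS small sub-threshold effects."""
    cats = list(config.category_mixture)
    probs = np.array([config.category_mixture[c] for c in cats], dtype=float)
    probs /= probs.sum()
    labels = rng.choice(len(cats), size=config.n_genes, p=probs)

    def mag(size):
        return rng.uniform(config.effect_low, config.effect_high, size)

    sign = np.where(rng.random(config.n_genes) < config.prob_a_up, 1.0, -1.0)
    c = np.zeros(config.n_genes)
    t = np.zeros(config.n_genes)
    for i, li in enumerate(labels):
        cat = cats[li]
        s = sign[i]
        if cat == Category.CIS:
            c[i] = s * mag(1)[0]
        elif cat == Category.TRANS:
            t[i] = s * mag(1)[0]
        elif cat == Category.CIS_PLUS_TRANS:
            c[i] = s * mag(1)[0]
            t[i] = s * mag(1)[0]
        elif cat == Category.CIS_X_TRANS:
            # opposite signs; keep |c| > |t| + 1 so P = c + t stays clearly
            # nonzero and the parental test retains power
            c[i] = s * (mag(1)[0] + 1.5)
            t[i] = -s * rng.uniform(
                config.effect_low, max(config.effect_low + 0.5, abs(c[i]) - 1.5)
            )
        elif cat == Category.COMPENSATING:
            c[i] = s * mag(1)[0]
            t[i] = -c[i]
        elif cat == Category.AMBIGUOUS:
            c[i] = s * rng.uniform(0.1, 0.6)
            t[i] = rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 0.6)
        # CONSERVED: c = t = 0
    truth_cat = [str(cats[li]) for li in labels]
    return truth_cat, c, t


def _gene_multipliers(
    n: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene gamma multipliers (mean 1, variance = dispersion).

    The multiplier is drawn once per gene and applied to every column, so
    each count is marginally negative binomial (variance mu + d mu^2)
    while within-gene ratios — the quantities the exact tests act on —
    stay binomially calibrated, emulating gene-level effects (capture,
    mappability, expression state) common to all libraries.
    """
    if dispersion == 0:
        return np.ones(n)
    shape = 1.0 / dispersion
    return rng.gamma(shape, dispersion, size=n)


def _generate(
    config: SimConfig,
    c_by_bc: Mapping[str, np.ndarray],
    t: np.ndarray,
    c_parent: np.ndarray,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[JointCounts, pd.DataFrame]:
    n = config.n_genes
    mu = np.exp(rng.normal(np.log(config.base_mean), config.base_sigma, n))
    silent = rng.random(n) < config.zero_gene_frac
    mu[silent] = 1.0
    truth = truth.copy()
    truth["base_mean"] = mu

    def depth(col):
        return config.depth_factors.get(col, 1.0)

    columns = {}
    pt = c_parent + t
    columns["parent_A"] = mu * 2.0 ** (pt / 2) * depth("parent_A")
    columns["parent_B"] = mu * 2.0 ** (-pt / 2) * depth("parent_B")
    for bc in config.backcrosses:
        f = config.fraction_for(bc)
        cb = c_by_bc[bc]
        columns[f"{bc}_A"] = mu * 2.0 ** (cb / 2) * f * 2 * depth(f"{bc}_A")
        columns[f"{bc}_B"] = mu * 2.0 ** (-cb / 2) * (1 - f) * 2 * depth(f"{bc}_B")

    gene_a = [f"GA{i:05d}" for i in range(n)]
    gene_b = [f"GB{i:05d}" for i in range(n)]
    data = pd.DataFrame({"gene_a": gene_a, "gene_b": gene_b})
    mult = _gene_multipliers(n, config.dispersion, rng)
    for name, mean in columns.items():
        data[name] = rng.poisson(np.clip(mean * mult, 1e-12, None)).astype("int64")
    data.index = pd.Index(
        data["gene_a"] + "|" + data["gene_b"], name="pair_id"
    )
    truth.index = data.index
    joint = JointCounts(
        data=data, backcrosses=tuple(config.backcrosses), normalized=False
    )
    return joint, truth


def simulate(config: SimConfig | None = None) -> tuple[JointCounts, pd.DataFrame]:
    """Generate a raw joint count matrix and its ground-truth table.

    The same per-gene (c, t) architecture drives every backcross, so a
    gene's true category is shared across backcrosses. Returns
    ``(JointCounts raw, truth)`` where truth has columns ``category``,
    ``c``, ``t`` and ``base_mean``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    cats, c, t = _draw_effects(config, rng)
    truth = pd.DataFrame({"category": cats, "c": c, "t": t})
    c_by_bc = {bc: c for bc in config.backcrosses}
    return _generate(config, c_by_bc, t, c, truth, rng)


def make_switching_scenario(
    config: SimConfig | None = None,
    n_switch: int = 50,
    split: tuple[int, int] | None = None,
) -> tuple[JointCounts, pd.DataFrame]:
    """Plant genes whose cis effect flips sign between the two backcrosses.

    ``n_switch`` genes (default 50) get a cis effect of one sign in the
    first backcross and the opposite sign in the second; ``split``
    partitions them into (A-then-B, B-then-A) planted directions (default
    an even split). Remaining genes follow the configured mixture. The
    truth table gains per-backcross cis columns and a
    ``switch_direction`` column ('' for non-switchers).
    """
    config = config or SimConfig()
    if len(config.backcrosses) != 2:
        raise ValueError("switching scenario needs exactly two backcrosses")
    if n_switch > config.n_genes:
        raise ValueError("cannot plant more switchers than genes")
    if split is None:
        split = (n_switch // 2, n_switch - n_switch // 2)
    if sum(split) != n_switch:
        raise ValueError(f"split {split} does not sum to n_switch={n_switch}")

    rng = np.random.default_rng(config.seed)
    cats, c, t = _draw_effects(config, rng)
    bc1, bc2 = config.backcrosses
    c1 = c.copy()
    c2 = c.copy()
    switch_dir = [""] * config.n_genes
    planted = rng.choice(config.n_genes, size=n_switch, replace=False)
    mags = rng.uniform(config.effect_low, config.effect_high, n_switch)
    for k, gi in enumerate(planted):
        a_first = k < split[0]
        s = 1.0 if a_first else -1.0
        c1[gi] = s * mags[k]
        c2[gi] = -s * mags[k]
        t[gi] = 0.0
        cats[gi] = str(Category.CIS)
        switch_dir[gi] = "A_to_B" if a_first else "B_to_A"
    truth = pd.DataFrame(
        {
            "category": cats,
            "c": c,
            f"c_{bc1}": c1,
            f"c_{bc2}": c2,
            "t": t,
            "switch_direction": switch_dir,
        }
    )
    joint, truth = _generate(
        config, {bc1: c1, bc2: c2}, t, c, truth, rng
    )
    return joint, truth
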