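# Methods

## The classification model

A backcross hybrid carries both parental alleles of each (still
heterozygous) gene in one nucleus. Trans-acting regulators — transcription
factors, signalling states — act on both alleles alike, so the log₂ allelic
ratio in the hybrid, H, reflects only cis (allele-linked) regulatory
divergence. The log₂ parental ratio P reflects cis and trans combined;
the trans component is estimated by subtraction, T = P − H.

Per gene, three tests are computed on integer normalized counts:

1. binomial exact test of the parent pair (x = parent-A count, n = pair
   total, p₀ = 0.5) — evidence that P ≠ 0;
2. the same test on the hybrid allele pair — evidence that H ≠ 0;
3. Fisher's exact test of the 2×2 table [parent A, parent B; hybrid A,
   hybrid B] — evidence that P ≠ H, i.e. a nonzero trans component.

Both exact tests use the minimum-likelihood two-sided convention (the
p-value sums all outcomes no more probable than the observed one) — the
convention of R's `binom.test`/`fisher.test`; at p₀ = 0.5 it coincides
with the doubled tail. Benjamini–Hochberg FDR is applied separately within
each of the three families, over the same retained gene set — each family
is one multiple-testing problem. With A/B/C the indicators q < α
(default α = 0.005) of tests 1–3:

| A | B | C | category        |
|---|---|---|-----------------|
| 0 | 0 | 0 | conserved       |
| 1 | 1 | 0 | cis             |
| 1 | 0 | 1 | trans           |
| 1 | 1 | 1 | cis + trans if sign(H)·sign(T) > 0; cis × trans if < 0; ambiguous on a sign tie |
| 0 | 1 | 1 | compensating    |
| other | | | ambiguous      |

Sign ties (H = 0 or T = 0 exactly, all three tests significant) go to
*ambiguous* rather than being silently called synergistic. The remaining
mixed patterns (only one test significant, or Fisher alone) are not
interpretable as a clean cis/trans architecture and are likewise
*ambiguous*.

Two category tables (one per backcross) are contrasted per category with a
2×2 chi-square test with Yates' continuity correction,
χ² = Σ max(|O−E|−0.5, 0)² / E, the correction clamped at zero so
near-null tables are never inflated. On the published category counts
(totals 9656 and 9295) this reproduces six of the seven published
statistics exactly at two decimals; the conserved row computes to 322.73
(R's `prop.test` agrees to seven decimals) against a printed 322.74,
a rounding slip in the printed table. The trans row's p-value computes to
0.3736.

## Normalization and filtering

Library-composition scaling uses the trimmed mean of M-values (TMM):
for column j against a reference column r (the column whose
upper-quartile depth-scaled count is closest to the mean upper quartile),
over genes nonzero in both, M = log₂((x_j/N_j)/(x_r/N_r)) and
A = ½ log₂(x_j x_r /(N_j N_r)); the top/bottom 30% by M and 5% by A are
discarded and the factor is 2 to the inverse-variance-weighted mean of M,
with delta-method variances v = (N−x)/(Nx) summed over the two columns
and weights 1/v. Factors are rescaled to geometric mean one. The
implementation matches edgeR's `calcNormFactors(method="TMM")` to nine
decimals on spiked test matrices (frozen oracle values in the test suite).
Fewer than 10 usable genes for a column triggers a warning and factor 1.

The exact tests need integer successes and trials, so normalized counts
are re-expressed on the mean effective library,
round(x_j /(N_j f_j) · mean(N f)), rounding half-away-from-zero. Zero
cells then receive a +1 pseudocount (only zeros — nonzero counts are
untouched), after which a pair is retained when its total is ≥ 20. TMM is
computed jointly across all columns of one joint matrix (parents plus all
backcross allele columns); the cross-backcross stage re-normalizes the
four backcross allele columns on their own, since the parents play no role
there.

## Allelic imbalance and incongruence

Per backcross, retained allele pairs get the binomial test and BH-FDR; a
gene is directional only under the dual threshold q < 0.05 **and**
|log₂FC| ≥ 1 (the biological threshold blocks statistically significant
but sub-2-fold imbalances). The genome–transcriptome incongruence test
compares the expected recurrent-genome fraction p (0.875 for BC2, 0.9375
for BC3, over a gene universe N per backcross — opaque study constants in
`RunConfig`) with the observed fraction x₂/n₂ of A-preferred genes among
the n₂ significant ones. The expected side enters the pooled variance as
an unrounded pseudo-count x₁ = p·N:

    p̂ = (p·N + x₂)/(N + n₂),
    z = (p − x₂/n₂) / √(p̂(1−p̂)(1/N + 1/n₂)),

two-tailed normal p. This pooling is the construction that reproduces both
published statistics (70.4 and 88.30) from their published inputs.

The cross-backcross stage runs both backcrosses' calls at the stricter
α = 0.005 (a separate config field from the per-backcross 0.05 — both
printed thresholds, not one knob) on the jointly re-normalized matrix,
keeping genes whose pseudocounted total reaches 20 in *either* backcross;
gene sets from different stages are never silently intersected. Joint
categories: conserved symmetric (neither significant), backcross-specific
(one), conserved asymmetric (both, same sign of log₂FC), switching (both,
opposite signs; direction A→B when the first backcross preferred A).

## The synthetic-data generator

The generator emulates the joint matrix the pipeline consumes. Per gene a
true category is drawn from a mixture (default: the architecture observed
in the abaca × banana system — 27.4% cis, 27.1% conserved, 30.5%
ambiguous, the rest split among trans and interactions), then cis and
trans log₂ effects c and t honouring the category's constraints
(conserved: c = t = 0; cis: t = 0; trans: c = 0; compensating: c = −t;
interactions: matching/opposite signs, with |c| > |t| for the
antagonistic class so P = c + t keeps the parental test powered).
Ambiguous genes get small sub-threshold effects (|effect| ~ U(0.1, 0.6)).
Nonzero magnitudes are uniform on [1, 3] log₂ units (2- to 8-fold) by
default; the sign favours allele A with probability `prob_a_up`
(default 0.5).

Expected counts split effects symmetrically so total expression is
effect-independent: parents μ·2^(±(c+t)/2); hybrid alleles μ·2^(±c/2)
scaled by 2·f and 2·(1−f) for an A-allele mapping fraction f
(default 0.5, balanced capture). Per-gene base means μ are lognormal
around `base_mean` (σ = 0.6 natural-log units); a small fraction
(default 2%) of genes is made near-silent to exercise the zero-row and
count filters; per-column depth multipliers emulate unequal library sizes.

Noise is gamma-Poisson: one gamma multiplier with mean 1 and variance
`dispersion` is drawn per gene and shared across all columns, then each
column is Poisson. Marginally every count is negative binomial
(variance μ + dμ²), but within-gene ratios stay binomially calibrated —
the regime the exact-test framework assumes. This models gene-level
effects common to all libraries (capture efficiency, mappability,
expression state). What it deliberately does not model: independent
biological variation between libraries, mapping bias between the two
reference assemblies, and ortholog misassignment. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under the
framework's own assumptions, not robustness of binomial calling to
between-library overdispersion on real data — with independent per-column
noise at these depths the binomial tests would flag nearly every gene, a
known limitation of replicate-free ASE designs.

`make_switching_scenario` plants a chosen number of genes (default 50)
whose cis effect flips sign between the two backcrosses, recording the
planted direction for recovery scoring.

## Numerical and design choices

- All thresholds live in `RunConfig` and are overridable; defaults are the
  published analysis settings (α = 0.005 for classification and the joint
  stage, 0.05 for per-backcross calls, |log₂FC| ≥ 1, min total 20).
- Zero-margin Fisher tables return p = 1 with a warning (no association
  is estimable); zero-margin chi-square tables are an error.
- All-zero ortholog rows are removed at assembly, before normalization.
- Ortholog maps must be strictly 1:1; resolving many-to-many clusters is
  the caller's responsibility and violations are rejected at read time.
- Gene ids match by exact string equality across files (the two reference
  assemblies use different naming systems; no prefix munging).
- Problem sizes in the test and acceptance runs: 2000 genes at base mean
  5000, dispersion 0.02, effects in [2, 3] log₂ units for recovery
  (recovery ≥ 95% for cis/trans/conserved in practice); 50 planted
  switchers; exhaustive exact-test oracles up to n = 25 (binomial) and row
  margins 12 (Fisher).

## Known limitations

- Pseudocounting only zero cells makes log-ratios of very low counts
  coarse; the ≥ 20 filter is the only guard, as in the replicate-free
  design the method targets.
- The incongruence z treats the expected genomic fraction as a
  pseudo-sample over the gene universe N; N itself is a study constant,
  not estimated.
- The classifier's *ambiguous* class mixes sign ties and mixed
  significance patterns; no attempt is made to resolve them further.
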