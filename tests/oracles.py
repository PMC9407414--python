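"""Brute-force enumeration oracles, independent of the implementations
they check: exact p-values are built directly from binomial / hypergeometric
point masses, and BH q-values from a literal reading of the step-up rule."""

from math import comb


def binom_pvalue_bruteforce(x: int, n: int, p0: float = 0.5) -> float:
    """Minimum-likelihood two-sided binomial p by full enumeration."""
    pmf = [comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)]
    obs = pmf[x]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-12)))


def fisher_pvalue_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided Fisher p by enumerating all tables with
    the observed margins (hypergeometric masses)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)
    }
    obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)))


def bh_bruteforce(pvals):
    """Literal BH step-up: q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, pvals[i] * m / rank))
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q
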