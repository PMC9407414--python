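"""Published summary numbers from the abaca (var. Abuab) x banana
(var. Pacol) backcross study these methods were developed for.

These are inputs for reproduction checks and worked examples — the
per-gene category counts of the two backcrosses, and the inputs of the two
genome–transcriptome incongruence z-tests. Allele A is the recurrent
parent (Abuab) throughout.
"""

from __future__ import annotations

from .regdiv import Category, CategoryCountTable

__all__ = [
    "BC2_CATEGORY_TABLE",
    "BC3_CATEGORY_TABLE",
    "INCONGRUENCE_INPUTS",
    "PUBLISHED_CHI2",
]

# Regulatory-category gene counts per backcross (retained totals 9656/9295).
BC2_CATEGORY_TABLE = CategoryCountTable(
    counts={
        Category.CIS: 2647,
        Category.CIS_PLUS_TRANS: 361,
        Category.CIS_X_TRANS: 478,
        Category.COMPENSATING: 441,
        Category.TRANS: 161,
        Category.AMBIGUOUS: 2955,
        Category.CONSERVED: 2613,
    },
    label="BC2",
)

BC3_CATEGORY_TABLE = CategoryCountTable(
    counts={
        Category.CIS: 2070,
        Category.CIS_PLUS_TRANS: 121,
        Category.CIS_X_TRANS: 14,
        Category.COMPENSATING: 203,
        Category.TRANS: 139,
        Category.AMBIGUOUS: 3090,
        Category.CONSERVED: 3658,
    },
    label="BC3",
)

# Inputs of the incongruence z-test: expected recurrent-genome fraction,
# gene-universe size, A-preferred calls, total significant ASE calls.
INCONGRUENCE_INPUTS = {
    "BC2": dict(genomic_prop=0.875, n_genome=33511, n_a=1703, n_sig=3971),
    "BC3": dict(genomic_prop=0.9375, n_genome=33394, n_a=1609, n_sig=3561),
}

# Published per-category Yates chi-square statistics (2 d.p.) comparing the
# two backcrosses' category counts.
PUBLISHED_CHI2 = {
    Category.CIS: 66.73,
    Category.CIS_PLUS_TRANS: 112.48,
    Category.CIS_X_TRANS: 429.55,
    Category.COMPENSATING: 81.21,
    Category.TRANS: 0.79,
    Category.AMBIGUOUS: 15.08,
    Category.CONSERVED: 322.74,
}
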