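"""Variant quality control: polymorphism, call rate and Hardy-Weinberg.

Three filters are applied in a fixed cheap-to-expensive order and each
removed variant is counted once, under the first rule that caught it:

1. monomorphic  — fewer than one copy of the minor allele among
   non-missing calls (cohort-wide);
2. call rate    — fraction of non-missing calls below ``min_callrate``;
3. HWE          — two-sided exact test p-value below ``hwe_alpha`` in any
   single population (testing within populations avoids spurious
   rejections from the Wahlund effect when diverged populations are
   pooled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_input: int
    n_removed_monomorphic: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_retained: int
    total_genotyping_rate: float

    def __post_init__(self):
        removed = (
            self.n_removed_monomorphic + self.n_removed_callrate + self.n_removed_hwe
        )
        if self.n_input != removed + self.n_retained:
            raise ValueError("QC counts do not add up")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, the probability of ``h``
    heterozygotes among ``N`` diploids is proportional to the multinomial
    weight ``N! / (n1! h! n2!) * 2**h`` over heterozygote counts of the
    same parity as the minor-allele count.  The p-value sums the
    probabilities of all configurations no more likely than the observed
    one.  Computed in exact integer arithmetic, so ties are resolved
    exactly.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("at least one genotyped individual is required")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    return _hwe_p_cached(n, n_minor, n_het)


@lru_cache(maxsize=200_000)
def _hwe_p_cached(n: int, n_minor: int, n_het: int) -> float:
    weights: dict[int, int] = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        weights[h] = comb(n, hom_minor) * comb(n - hom_minor, h) * (1 << h)
    obs = weights[n_het]
    num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, sum(weights.values())))


def genotype_counts(matrix: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """Per-variant (hom_ref, het, hom_alt) counts over the given rows."""
    calls = matrix.calls[rows]
    return np.stack(
        [(calls == g).sum(axis=0) for g in (HOM_REF, HET, HOM_ALT)], axis=1
    )


def filter_variants(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    min_callrate: float = 0.1,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame, QCReport]:
    """Apply the three-rule variant filter; returns the retained subset."""
    if matrix.n_variants != len(variants):
        raise ValueError("matrix and variant table have inconsistent dimensions")
    calls = matrix.calls
    n_ind = matrix.n_individuals
    nonmiss = calls >= 0
    n_nonmiss = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    total_alleles = 2 * n_nonmiss
    mac = np.minimum(alt, total_alleles - alt)
    monomorphic = mac < 1

    callrate = n_nonmiss / n_ind
    low_callrate = (callrate < min_callrate) & ~monomorphic

    remaining = ~(monomorphic | low_callrate)
    hwe_fail = np.zeros(matrix.n_variants, dtype=bool)
    idx_remaining = np.nonzero(remaining)[0]
    for pop in matrix.population_names():
        counts = genotype_counts(matrix, matrix.population_rows(pop))[idx_remaining]
        pvals = np.array(
            [
                hwe_exact_test(int(a), int(b), int(c)) if a + b + c > 0 else 1.0
                for a, b, c in counts
            ]
        )
        hwe_fail[idx_remaining[pvals < hwe_alpha]] = True

    keep = remaining & ~hwe_fail
    out = matrix.subset_variants(keep)
    out_variants = variants.loc[keep].reset_index(drop=True)
    rate = (
        float(nonmiss[:, keep].mean()) if keep.any() else 0.0
    )
    report = QCReport(
        n_input=matrix.n_variants,
        n_removed_monomorphic=int(monomorphic.sum()),
        n_removed_callrate=int(low_callrate.sum()),
        n_removed_hwe=int(hwe_fail.sum()),
        n_retained=int(keep.sum()),
        total_genotyping_rate=rate,
    )
    if report.n_retained == 0:
        logger.warning("all variants removed by QC")
    logger.info(
        "QC: %d in, %d monomorphic, %d low call rate, %d HWE, %d retained",
        report.n_input, report.n_removed_monomorphic, report.n_removed_callrate,
        report.n_removed_hwe, report.n_retained,
    )
    return out, out_variants, report
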