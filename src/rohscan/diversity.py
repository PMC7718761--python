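"""Per-population diversity metrics and Wright's inbreeding coefficient.

Observed heterozygosity (Ho) is the per-individual fraction of
heterozygous calls among non-missing calls.  Expected heterozygosity
(He) is the per-variant 2p(1-p) from within-population allele
frequencies, without small-sample correction.  The "polymorphic marker
ratio" (PN) is, operationally, the mean over individuals of the
proportion of non-missing calls at the sites that are polymorphic in
that population, expressed as a percentage.

Wright's F_is for individual i is

    F_is = (O_i - E_i) / (L_i - E_i)

where O_i is the observed homozygote count over the individual's L_i
non-missing sites and E_i sums the expected homozygosity
1 - 2p(1-p) * 2n/(2n-1) over those sites (n = number of non-missing
diploids in the population at the site; the 2n/(2n-1) factor is the
usual method-of-moments small-sample correction, which centers F_is at
zero under Hardy-Weinberg equilibrium).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET

logger = logging.getLogger(__name__)


def _pop_freq_and_n(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ALT frequency and non-missing diploid count."""
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
    return p, n


def observed_heterozygosity(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual Ho = het calls / non-missing calls."""
    nonmiss = (matrix.calls >= 0).sum(axis=1)
    het = (matrix.calls == HET).sum(axis=1)
    zero = np.nonzero(nonmiss == 0)[0]
    if zero.size:
        raise ValueError(
            f"individual(s) with no non-missing calls: "
            f"{[matrix.samples[i] for i in zero]}"
        )
    return pd.DataFrame(
        {
            "individual": matrix.samples,
            "population": matrix.populations,
            "ho": het / nonmiss,
        }
    )


def expected_heterozygosity(matrix: GenotypeMatrix, population: str) -> pd.DataFrame:
    """Per-variant He = 2p(1-p) within one population.

    Variants with no non-missing call in the population are excluded.
    Requires at least two individuals.
    """
    rows = matrix.population_rows(population)
    if rows.size < 2:
        raise ValueError(f"population {population!r} needs >= 2 individuals")
    p, n = _pop_freq_and_n(matrix.calls[rows])
    keep = n > 0
    he = 2 * p[keep] * (1 - p[keep])
    return pd.DataFrame({"variant_index": np.nonzero(keep)[0], "he": he})


def polymorphic_sites(matrix: GenotypeMatrix, population: str) -> np.ndarray:
    """Boolean mask of variants segregating within the population."""
    rows = matrix.population_rows(population)
    calls = matrix.calls[rows]
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    return (alt > 0) & (alt < 2 * n)


def polymorphic_ratio(
    matrix: GenotypeMatrix, variants: pd.DataFrame, population: str
) -> pd.DataFrame:
    """Per-individual % of non-missing calls at the population's
    polymorphic sites."""
    poly = polymorphic_sites(matrix, population)
    if not poly.any():
        raise ValueError(f"no polymorphic sites in population {population!r}")
    rows = matrix.population_rows(population)
    frac = (matrix.calls[rows][:, poly] >= 0).mean(axis=1) * 100.0
    return pd.DataFrame(
        {"individual": [matrix.samples[i] for i in rows], "pn": frac}
    )


def wright_fis(matrix: GenotypeMatrix, population: str) -> pd.DataFrame:
    """Per-individual F_is within one population (may be negative, or NaN
    with a warning where the denominator vanishes)."""
    rows = matrix.population_rows(population)
    calls = matrix.calls[rows]
    p, n = _pop_freq_and_n(calls)
    usable = n > 0
    with np.errstate(invalid="ignore"):
        exp_hom = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0)
    exp_hom = np.where(usable, exp_hom, 0.0)

    nonmiss = (calls >= 0) & usable[None, :]
    hom = nonmiss & (calls != HET)
    O = hom.sum(axis=1).astype(float)
    L = nonmiss.sum(axis=1).astype(float)
    E = nonmiss @ exp_hom
    denom = L - E
    fis = np.full(len(rows), np.nan)
    ok = np.abs(denom) > 1e-12
    fis[ok] = (O[ok] - E[ok]) / denom[ok]
    if not ok.all():
        logger.warning(
            "F_is undefined (L == E) for %d individual(s) in %s",
            int((~ok).sum()), population,
        )
    return pd.DataFrame(
        {"individual": [matrix.samples[i] for i in rows], "fis": fis}
    )


def diversity_summary(matrix: GenotypeMatrix, variants: pd.DataFrame) -> pd.DataFrame:
    """Per-population summary: N, polymorphic sites, Ho, He, PN, F_is."""
    ho = observed_heterozygosity(matrix)
    out = []
    for pop in matrix.population_names():
        rows = matrix.population_rows(pop)
        he = expected_heterozygosity(matrix, pop)["he"]
        pn = polymorphic_ratio(matrix, variants, pop)["pn"]
        fis = wright_fis(matrix, pop)["fis"]
        ho_pop = ho.loc[ho["population"] == pop, "ho"]
        out.append(
            {
                "population": pop,
                "n_individuals": int(rows.size),
                "n_polymorphic_sites": int(polymorphic_sites(matrix, pop).sum()),
                "ho_mean": float(ho_pop.mean()),
                "ho_sd": float(ho_pop.std(ddof=1)) if len(ho_pop) > 1 else 0.0,
                "he_mean": float(he.mean()),
                "he_sd": float(he.std(ddof=1)) if len(he) > 1 else 0.0,
                "pn_mean": float(pn.mean()),
                "pn_sd": float(pn.std(ddof=1)) if len(pn) > 1 else 0.0,
                "fis_mean": float(fis.mean()),
                "fis_max": float(fis.max()),
                "fis_min": float(fis.min()),
            }
        )
    return pd.DataFrame(out)
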