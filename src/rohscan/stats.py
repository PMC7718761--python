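"""ROH summary statistics: length classes, chromosome coverage and F_ROH.

Segments are binned into seven contiguous length classes (0.3-1, 1-2,
2-4, 4-8, 8-10, 10-16 and >16 Mb), left-closed right-open.  The genomic
inbreeding coefficient of an individual is

    F_ROH = L_ROH / L_total

the summed ROH length divided by the autosomal genome size covered by
SNPs (default 931 Mb, the chicken autosomal assembly size); per-class
F_ROH uses only the segments falling in that class, so the class values
sum to the total exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import ROHSet
from .simulate import GenomeLayout, LENGTH_CLASS_BINS_MB

logger = logging.getLogger(__name__)

#: default autosomal genome size in bp (chicken assembly scale)
DEFAULT_GENOME_BP = 931_000_000

CLASS_LABELS = ["0.3-1Mb", "1-2Mb", "2-4Mb", "4-8Mb", "8-10Mb", "10-16Mb", ">16Mb"]
_CLASS_EDGES_BP = [lo * 1e6 for lo, _ in LENGTH_CLASS_BINS_MB] + [np.inf]


@dataclass(frozen=True)
class GenomeSize:
    l_total: int = DEFAULT_GENOME_BP

    def __post_init__(self):
        if self.l_total <= 0:
            raise ValueError("genome size must be positive")


def _class_of(length_bp: float) -> int:
    """Index of the left-closed right-open length class; <0.3 Mb is an error."""
    if length_bp < _CLASS_EDGES_BP[0]:
        raise ValueError(
            f"segment of {length_bp} bp is below the smallest class (0.3 Mb)"
        )
    return int(np.searchsorted(_CLASS_EDGES_BP, length_bp, side="right") - 1)


def classify_lengths(rohset: ROHSet) -> pd.DataFrame:
    """Length-class summary per population.

    One row per population: per-class counts and percentages (of the
    population's total), total/mean segment numbers and total/max/min
    lengths in Mb.
    """
    pops = list(dict.fromkeys(p for _, p in rohset.individuals))
    pop_sizes = {p: sum(1 for _, q in rohset.individuals if q == p) for p in pops}
    counts = {p: np.zeros(len(CLASS_LABELS), dtype=int) for p in pops}
    lengths: dict[str, list[int]] = {p: [] for p in pops}
    for s in rohset.segments:
        if s.population not in counts:
            pops.append(s.population)
            pop_sizes[s.population] = 0
            counts[s.population] = np.zeros(len(CLASS_LABELS), dtype=int)
            lengths[s.population] = []
        counts[s.population][_class_of(s.length)] += 1
        lengths[s.population].append(s.length)

    rows = []
    for p in pops:
        total = int(counts[p].sum())
        row: dict = {"population": p, "n_individuals": pop_sizes[p]}
        for k, lab in enumerate(CLASS_LABELS):
            row[f"n_{lab}"] = int(counts[p][k])
            row[f"pct_{lab}"] = 100.0 * counts[p][k] / total if total else 0.0
        row["total_n"] = total
        row["mean_n"] = total / pop_sizes[p] if pop_sizes[p] else float("nan")
        lens = np.array(lengths[p], dtype=float)
        row["total_length_mb"] = float(lens.sum() / 1e6) if total else 0.0
        row["max_mb"] = float(lens.max() / 1e6) if total else 0.0
        row["min_mb"] = float(lens.min() / 1e6) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def per_individual_summary(rohset: ROHSet) -> pd.DataFrame:
    """Per-individual segment count and summed length (zero if none)."""
    base = {
        ind: {"individual": ind, "population": pop, "total_n": 0, "total_length_bp": 0}
        for ind, pop in rohset.individuals
    }
    for s in rohset.segments:
        rec = base.setdefault(
            s.individual,
            {"individual": s.individual, "population": s.population,
             "total_n": 0, "total_length_bp": 0},
        )
        rec["total_n"] += 1
        rec["total_length_bp"] += s.length
    return pd.DataFrame(list(base.values()))


def f_roh(
    rohset: ROHSet,
    genome: GenomeSize = GenomeSize(),
) -> pd.DataFrame:
    """Per-individual F_ROH, total and per length class.

    Emits a warning (not an error) if any individual's summed ROH length
    exceeds the configured genome size.
    """
    recs = {
        ind: {"individual": ind, "population": pop,
              **{f"froh_{lab}": 0.0 for lab in CLASS_LABELS}}
        for ind, pop in rohset.individuals
    }
    for s in rohset.segments:
        rec = recs.setdefault(
            s.individual,
            {"individual": s.individual, "population": s.population,
             **{f"froh_{lab}": 0.0 for lab in CLASS_LABELS}},
        )
        rec[f"froh_{CLASS_LABELS[_class_of(s.length)]}"] += s.length / genome.l_total
    df = pd.DataFrame(list(recs.values()))
    df["froh_total"] = df[[f"froh_{lab}" for lab in CLASS_LABELS]].sum(axis=1)
    if (df["froh_total"] > 1.0).any():
        warnings.warn(
            "total ROH length exceeds the configured genome size for some "
            "individuals; check GenomeSize", stacklevel=2,
        )
    return df


def chromosome_coverage(rohset: ROHSet, layout: GenomeLayout) -> pd.DataFrame:
    """Per population x chromosome: segment count, mean length and the
    mean (over all individuals of the population) % of the chromosome
    covered by ROH."""
    known = {name for name, _ in layout.chromosomes}
    for s in rohset.segments:
        if s.chromosome not in known:
            raise ValueError(f"segment on unknown chromosome {s.chromosome!r}")
    pops = list(dict.fromkeys(p for _, p in rohset.individuals))
    pop_sizes = {p: sum(1 for _, q in rohset.individuals if q == p) for p in pops}

    cov: dict[tuple[str, str], dict[str, float]] = {}
    per_ind_cov: dict[tuple[str, str], float] = {}
    for s in rohset.segments:
        key = (s.population, s.chromosome)
        d = cov.setdefault(key, {"n_roh": 0, "length_sum": 0.0})
        d["n_roh"] += 1
        d["length_sum"] += s.length
        # segments of one individual on one chromosome are disjoint, so
        # summed length equals the covered length
        per_ind_cov[(s.individual, s.chromosome)] = (
            per_ind_cov.get((s.individual, s.chromosome), 0.0) + s.length
        )

    rows = []
    for p in pops:
        members = [ind for ind, q in rohset.individuals if q == p]
        for name, length in layout.chromosomes:
            d = cov.get((p, name), {"n_roh": 0, "length_sum": 0.0})
            covered = [per_ind_cov.get((ind, name), 0.0) for ind in members]
            rows.append(
                {
                    "population": p,
                    "chrom": name,
                    "n_roh": int(d["n_roh"]),
                    "mean_length_mb": d["length_sum"] / d["n_roh"] / 1e6
                    if d["n_roh"] else 0.0,
                    "percent_covered": 100.0 * float(np.mean(covered)) / length
                    if members else 0.0,
                }
            )
    return pd.DataFrame(rows)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def froh_population_summary(froh: pd.DataFrame) -> pd.DataFrame:
    """Population means of per-class and total F_ROH, with the SD of the
    total over individuals."""
    cols = [f"froh_{lab}" for lab in CLASS_LABELS] + ["froh_total"]
    g = froh.groupby("population", sort=False)
    out = g[cols].mean().reset_index()
    out["froh_sd"] = g["froh_total"].std(ddof=1).to_numpy()
    out["n_individuals"] = g.size().to_numpy()
    return out
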