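"""Synthetic multi-population cohorts with planted autozygous tracts.

The generator is a deliberately simple stand-in for real sequence-derived
genotypes: per-SNP allele frequencies are drawn from a symmetric Beta
distribution tuned so that expected heterozygosity 2p(1-p) matches a
population's target, genotypes are sampled under Hardy-Weinberg
proportions at each site independently (no linkage disequilibrium), and
autozygosity is introduced by overwriting intervals with a single founder
haplotype in homozygous state.  Sporadic heterozygous and missing calls
can be injected inside tracts to mimic the genotyping noise that breaks
long runs of homozygosity into shorter tracts in sequence data.

Ground truth (the planted intervals) is returned alongside the genotype
matrix so downstream detectors can be scored against it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    GenomicInterval,
    GenotypeMatrix,
    HET,
    MISSING,
    make_variant_table,
)

#: canonical ROH length-class bins in Mb; ``None`` upper bound = open-ended
LENGTH_CLASS_BINS_MB: tuple[tuple[float, float | None], ...] = (
    (0.3, 1.0),
    (1.0, 2.0),
    (2.0, 4.0),
    (4.0, 8.0),
    (8.0, 10.0),
    (10.0, 16.0),
    (16.0, None),
)

#: sampling cap for the open-ended >16 Mb class (Mb)
_OPEN_CLASS_CAP_MB = 20.0

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome structure of the simulated genome."""

    chromosomes: tuple[tuple[str, int], ...]
    snp_density: float  # mean SNPs per bp

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


@dataclass(frozen=True)
class PopulationProfile:
    """Generating parameters for one population.

    ``tract_length_distribution`` maps each canonical length-class bin
    (Mb bounds, ``None`` = open-ended) to the expected number of planted
    tracts per individual in that class; counts are Poisson-distributed.
    """

    name: str
    n_individuals: int
    target_het: float
    missing_rate: float = 0.0
    within_tract_het_rate: float = 0.0
    tract_length_distribution: tuple[tuple[tuple[float, float | None], float], ...] = ()

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for r, nm in (
            (self.target_het, "target_het"),
            (self.missing_rate, "missing_rate"),
            (self.within_tract_het_rate, "within_tract_het_rate"),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.target_het >= 0.5 and self.target_het != 0.5:
            raise ValueError("target_het cannot exceed 0.5 for biallelic sites")
        for bounds, count in self.tract_length_distribution:
            if bounds not in LENGTH_CLASS_BINS_MB:
                raise ValueError(f"non-canonical tract length class: {bounds}")
            if count < 0:
                raise ValueError("expected tract counts must be non-negative")


@dataclass(frozen=True)
class TruthTract:
    """A planted autozygous interval (ground truth for recovery tests)."""

    individual: str
    interval: GenomicInterval


def default_layout() -> GenomeLayout:
    """Desk-scale three-chromosome genome: macro / intermediate / micro.

    50 + 20 + 5 Mb at 1 SNP / 5 kb, about 15,000 SNPs in total.
    """
    return GenomeLayout(
        chromosomes=(("chr1", 50_000_000), ("chr2", 20_000_000), ("chr3", 5_000_000)),
        snp_density=1.0 / 5_000,
    )


def default_profiles() -> tuple[PopulationProfile, ...]:
    """Five populations emulating two layer lines, two broiler lines and a
    wild reference: layer-like populations carry a heavy burden of short
    tracts, the wild-like population few but proportionally longer ones.

    Target heterozygosities follow the observed range (0.24-0.31); tract
    burdens are scaled to the desk genome so that merging of independently
    placed tracts stays rare.
    """
    b = LENGTH_CLASS_BINS_MB
    return (
        PopulationProfile(
            "WL", 25, 0.278, 0.02, 0.005,
            ((b[0], 12.0), (b[1], 4.0), (b[2], 1.2), (b[3], 0.15)),
        ),
        PopulationProfile(
            "BL", 25, 0.282, 0.02, 0.005,
            ((b[0], 7.0), (b[1], 3.0), (b[2], 1.5), (b[3], 0.5), (b[4], 0.06),
             (b[5], 0.05), (b[6], 0.01)),
        ),
        PopulationProfile(
            "BRA", 20, 0.296, 0.02, 0.005,
            ((b[0], 4.0), (b[1], 1.0), (b[2], 0.5), (b[3], 0.12), (b[4], 0.01),
             (b[5], 0.008)),
        ),
        PopulationProfile(
            "BRB", 20, 0.309, 0.02, 0.005,
            ((b[0], 4.5), (b[1], 1.2), (b[2], 0.55), (b[3], 0.12), (b[4], 0.006)),
        ),
        PopulationProfile(
            "RJF", 25, 0.240, 0.02, 0.005,
            ((b[0], 1.6), (b[1], 0.75), (b[2], 0.5), (b[3], 0.23), (b[4], 0.025),
             (b[5], 0.018), (b[6], 0.002)),
        ),
    )


def _beta_shape(target_het: float) -> float:
    # symmetric Beta(a, a): E[2p(1-p)] = 0.5 - 1/(2(2a+1)); solve for a
    return target_het / (1.0 - 2.0 * target_het)


def _draw_frequencies(rng: np.random.Generator, n: int, target_het: float) -> np.ndarray:
    if target_het == 0.0:
        return rng.integers(0, 2, size=n).astype(float)
    if target_het == 0.5:
        return np.full(n, 0.5)
    a = _beta_shape(target_het)
    return rng.beta(a, a, size=n)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    merged = [ivals[0]]
    for s, e in ivals[1:]:
        ls, le = merged[-1]
        if s < le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _sample_positions(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    n = int(round(length * density))
    pos = np.unique(rng.integers(1, length + 1, size=n))
    return pos


def simulate_cohort(
    layout: GenomeLayout,
    profiles: list[PopulationProfile] | tuple[PopulationProfile, ...],
    seed: int,
) -> tuple[GenotypeMatrix, pd.DataFrame, list[TruthTract]]:
    """Simulate a multi-population cohort with planted autozygous tracts.

    Returns the genotype matrix, the variant table and the list of planted
    tracts (overlapping tracts within one individual are merged, with a
    warning).  The same seed always yields identical output.
    """
    if not layout.chromosomes:
        raise ValueError("layout must contain at least one chromosome")
    if not profiles:
        raise ValueError("at least one population profile is required")
    rng = np.random.default_rng(seed)

    # shared variant scaffold
    chroms, positions = [], []
    for name, length in layout.chromosomes:
        pos = _sample_positions(rng, length, layout.snp_density)
        positions.append(pos)
        chroms.extend([name] * len(pos))
    pos_all = np.concatenate(positions)
    n_snps = len(pos_all)
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    variants = make_variant_table(
        chroms, pos_all, ref=_BASES[ref_idx], alt=_BASES[alt_idx]
    )
    chrom_slices: dict[str, slice] = {}
    positions_by_chrom: dict[str, np.ndarray] = {}
    off = 0
    for (name, _), pos in zip(layout.chromosomes, positions):
        chrom_slices[name] = slice(off, off + len(pos))
        positions_by_chrom[name] = pos
        off += len(pos)

    call_blocks, samples, pops, truth = [], [], [], []
    for profile in profiles:
        freqs = _draw_frequencies(rng, n_snps, profile.target_het)
        calls = rng.binomial(2, freqs, size=(profile.n_individuals, n_snps)).astype(np.int8)
        for k in range(profile.n_individuals):
            indiv = f"{profile.name}_{k + 1:03d}"
            samples.append(indiv)
            pops.append(profile.name)
            tracts = _plant_tracts(rng, layout, profile, freqs, calls[k],
                                   chrom_slices, positions_by_chrom)
            truth.extend(TruthTract(indiv, iv) for iv in tracts)
        if profile.missing_rate > 0:
            miss = rng.random(calls.shape) < profile.missing_rate
            calls[miss] = MISSING
        call_blocks.append(calls)

    matrix = GenotypeMatrix(np.concatenate(call_blocks, axis=0), samples, pops)
    return matrix, variants, truth


def _plant_tracts(rng, layout, profile, freqs, row, chrom_slices, positions_by_chrom):
    """Plant this individual's tracts in-place; return merged truth intervals."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    max_len = max(length for _, length in layout.chromosomes)
    weights = np.array([length for _, length in layout.chromosomes], dtype=float)
    names = [name for name, _ in layout.chromosomes]
    for (lo_mb, hi_mb), expected in profile.tract_length_distribution:
        hi_mb_eff = hi_mb if hi_mb is not None else min(_OPEN_CLASS_CAP_MB, max_len / 1e6)
        for _ in range(rng.poisson(expected)):
            tract_len = int(rng.uniform(lo_mb, hi_mb_eff) * 1e6)
            if tract_len > max_len:
                raise ValueError(
                    f"tract of {tract_len} bp exceeds every chromosome in the layout"
                )
            fit = np.array([layout.length_of(n) >= tract_len for n in names])
            w = weights * fit
            chrom = names[rng.choice(len(names), p=w / w.sum())]
            start = int(rng.integers(0, layout.length_of(chrom) - tract_len + 1))
            per_chrom.setdefault(chrom, []).append((start, start + tract_len))

    merged_truth: list[GenomicInterval] = []
    for chrom, ivals in per_chrom.items():
        merged = _merge_intervals(ivals)
        if len(merged) < len(ivals):
            warnings.warn(
                f"merged {len(ivals) - len(merged)} overlapping planted tracts "
                f"on {chrom}", stacklevel=2,
            )
        pos = positions_by_chrom[chrom]
        base = chrom_slices[chrom].start
        for s, e in merged:
            # SNP at 1-based position P lies in [s, e) iff s < P <= e
            lo = int(np.searchsorted(pos, s + 1, side="left"))
            hi = int(np.searchsorted(pos, e, side="right"))
            idx = np.arange(base + lo, base + hi)
            if idx.size:
                founder = rng.binomial(1, freqs[idx])
                row[idx] = (2 * founder).astype(np.int8)
                if profile.within_tract_het_rate > 0:
                    flip = rng.random(idx.size) < profile.within_tract_het_rate
                    row[idx[flip]] = HET
            merged_truth.append(GenomicInterval(chrom, s, e))
    return merged_truth


def write_truth_bed(truth: list[TruthTract], path) -> None:
    """Write planted tracts as BED (0-based half-open), one line per tract."""
    with open(path, "w") as fh:
        for t in truth:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.individual}\n")


def write_chromosome_lengths(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_chromosome_lengths(path) -> GenomeLayout:
    """Read a two-column (name, length) TSV as a layout.

    ``snp_density`` is not recoverable from the table; a nominal value is
    stored since downstream consumers only need chromosome lengths.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split()[:2]
                rows.append((name, int(length)))
    return GenomeLayout(chromosomes=tuple(rows), snp_density=1.0 / 5_000)
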