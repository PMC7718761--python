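"""Sliding-window detection of runs of homozygosity (ROH).

The scan follows the classic window-based genotype algorithm: a window
of ``window_snps`` consecutive SNPs is called homozygous when it
contains at most ``window_max_het`` heterozygous and at most
``window_max_missing`` missing calls.  Each SNP's hit rate is the
fraction of windows containing it that are homozygous (SNPs near
chromosome ends have fewer containing windows; a chromosome shorter
than one window is treated as a single whole-chromosome window).  A SNP
is flagged when its hit rate reaches ``hit_proportion`` and its own call
is not heterozygous — missing calls may be flagged, since absence of a
call is not evidence against homozygosity.  Maximal runs of flagged
SNPs are split wherever adjacent flagged SNPs lie more than
``max_gap_kb`` apart, and each run is reported as a segment if it has at
least ``min_snps`` SNPs, spans at least ``min_length_kb``, and averages
no more than ``min_density_kb_per_snp`` kb per SNP.

Segment coordinates are the 1-based positions of the first and last
flagged SNP; length = end - start + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, MISSING

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    """Sliding-window scan parameters (defaults are the conventional
    whole-genome-sequence settings)."""

    window_snps: int = 50
    window_max_het: int = 3
    window_max_missing: int = 5
    hit_proportion: float = 0.05
    min_snps: int = 50
    min_length_kb: float = 300.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self):
        for name in (
            "window_snps", "window_max_het", "window_max_missing", "min_snps",
            "min_length_kb", "max_gap_kb", "min_density_kb_per_snp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.hit_proportion <= 1.0:
            raise ValueError("hit_proportion must lie in (0, 1]")
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValueError("window_snps and min_snps must be >= 1")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run of one individual on one chromosome."""

    individual: str
    population: str
    chromosome: str
    start: int  # 1-based position of first SNP
    end: int    # 1-based position of last SNP
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ROHSet:
    """All segments of a cohort plus the scan parameters and the cohort
    roster (so individuals without any segment still enter statistics)."""

    segments: list[ROHSegment]
    params: ScanParams
    individuals: list[tuple[str, str]] = field(default_factory=list)  # (id, population)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "individual": s.individual,
                "population": s.population,
                "chrom": s.chromosome,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "length_bp": s.length,
            }
            for s in self.segments
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "individual", "population", "chrom", "start", "end",
                "n_snps", "length_bp",
            ],
        )


def window_hit_rates(calls: np.ndarray, params: ScanParams) -> np.ndarray:
    """Per-SNP fraction of containing windows that are homozygous."""
    calls = np.asarray(calls)
    n = len(calls)
    if n == 0:
        raise ValueError("empty call vector")
    w = min(params.window_snps, n)

    het = np.concatenate(([0], np.cumsum(calls == HET)))
    mis = np.concatenate(([0], np.cumsum(calls == MISSING)))
    win_het = het[w:] - het[:-w]            # window starting at i covers [i, i+w)
    win_mis = mis[w:] - mis[:-w]
    win_ok = (win_het <= params.window_max_het) & (win_mis <= params.window_max_missing)

    ok_prefix = np.concatenate(([0], np.cumsum(win_ok)))
    i = np.arange(n)
    first = np.maximum(0, i - w + 1)        # first window index containing SNP i
    last = np.minimum(i, n - w)             # last window index containing SNP i
    n_windows = last - first + 1
    n_ok = ok_prefix[last + 1] - ok_prefix[first]
    return n_ok / n_windows


def call_roh(
    calls: np.ndarray,
    positions: np.ndarray,
    params: ScanParams = ScanParams(),
    individual: str = "",
    population: str = "",
    chromosome: str = "",
) -> list[ROHSegment]:
    """Call ROH segments for one individual on one chromosome."""
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    if len(calls) != len(positions):
        raise ValueError("calls and positions differ in length")
    if len(positions) > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")

    rates = window_hit_rates(calls, params)
    flagged = (rates >= params.hit_proportion) & (calls != HET)

    segments: list[ROHSegment] = []
    max_gap = params.max_gap_kb * 1000.0
    idx = np.nonzero(flagged)[0]
    if idx.size == 0:
        return segments
    # break runs at unflagged SNPs or at physical gaps > max_gap
    breaks = np.nonzero(
        (np.diff(idx) > 1) | (np.diff(positions[idx]) > max_gap)
    )[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        lo, hi = idx[a], idx[b]
        n_snps = hi - lo + 1
        length = int(positions[hi] - positions[lo] + 1)
        if n_snps < params.min_snps:
            continue
        if length < params.min_length_kb * 1000.0:
            continue
        if length / n_snps > params.min_density_kb_per_snp * 1000.0:
            continue
        segments.append(
            ROHSegment(
                individual=individual,
                population=population,
                chromosome=chromosome,
                start=int(positions[lo]),
                end=int(positions[hi]),
                n_snps=int(n_snps),
            )
        )
    return segments


def scan_cohort(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    params: ScanParams = ScanParams(),
) -> ROHSet:
    """Run the ROH scan for every individual on every chromosome."""
    if matrix.n_variants != len(variants):
        raise ValueError("matrix and variant table have inconsistent dimensions")
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    chrom_order = list(dict.fromkeys(chrom_arr))
    slices = {}
    for c in chrom_order:
        j = np.nonzero(chrom_arr == c)[0]
        slices[c] = (j, pos_arr[j])

    segments: list[ROHSegment] = []
    for i, (sample, pop) in enumerate(zip(matrix.samples, matrix.populations)):
        for c in chrom_order:
            j, pos = slices[c]
            if j.size == 0:
                continue
            segments.extend(
                call_roh(
                    matrix.calls[i, j], pos, params,
                    individual=sample, population=pop, chromosome=c,
                )
            )
    rohset = ROHSet(
        segments=segments,
        params=params,
        individuals=list(zip(matrix.samples, matrix.populations)),
    )
    totals: dict[str, int] = {}
    for s in segments:
        totals[s.population] = totals.get(s.population, 0) + 1
    logger.info("ROH scan: %s", totals or "no segments")
    return rohset


def write_segments_tsv(rohset: ROHSet, path) -> None:
    """Segment table (one row per ROH) with lengths in kb."""
    df = rohset.to_frame()
    df["length_kb"] = df["length_bp"] / 1000.0
    df.drop(columns="length_bp").to_csv(path, sep="\t", index=False,
                                        float_format="%.3f")


def write_segments_bed(rohset: ROHSet, path) -> None:
    """Segments as BED (0-based half-open), name = individual."""
    with open(path, "w") as fh:
        for s in rohset.segments:
            fh.write(f"{s.chromosome}\t{s.start - 1}\t{s.end}\t{s.individual}\n")


def read_segments_tsv(path, params: ScanParams = ScanParams(),
                      individuals: list[tuple[str, str]] | None = None) -> ROHSet:
    df = pd.read_csv(path, sep="\t")
    segments = [
        ROHSegment(
            individual=str(r.individual), population=str(r.population),
            chromosome=str(r.chrom), start=int(r.start), end=int(r.end),
            n_snps=int(r.n_snps),
        )
        for r in df.itertuples()
    ]
    if individuals is None:
        individuals = list(dict.fromkeys((s.individual, s.population) for s in segments))
    return ROHSet(segments=segments, params=params, individuals=individuals)
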