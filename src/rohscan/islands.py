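"""ROH islands: per-SNP incidence, thresholding and interval overlap.

The incidence of a SNP in a population is the fraction of individuals
with at least one ROH covering its position.  An island-calling
threshold is taken as the incidence of the ``ceil(top_fraction * n)``-th
most-covered SNP (a nearest-rank order statistic — incidence takes at
most N+1 discrete values for N individuals, so interpolation would be
meaningless), which makes the threshold population-specific: highly
inbred populations yield high thresholds, diverse ones low.  Islands
are maximal runs of at least two adjacent SNPs at or above the
threshold, broken at large physical gaps.
"""

from __future__ import annotations

import bisect
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import ROHSet
from .genotypes import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHIsland:
    chromosome: str
    start: int  # 1-based position of first member SNP
    end: int    # 1-based position of last member SNP
    n_snps: int
    mean_incidence: float
    population: str

    def to_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start - 1, self.end,
                               label=self.population)


def snp_incidence(
    rohset: ROHSet, variants: pd.DataFrame, population: str
) -> pd.DataFrame:
    """Per-SNP fraction of the population's individuals whose ROH cover it."""
    members = [ind for ind, p in rohset.individuals if p == population]
    if not members:
        raise ValueError(f"unknown or empty population: {population!r}")
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    count = np.zeros(len(variants), dtype=np.int64)
    chrom_index: dict[str, np.ndarray] = {}
    for c in dict.fromkeys(chrom_arr):
        chrom_index[c] = np.nonzero(chrom_arr == c)[0]
    # segments of one individual are disjoint, so += 1 per segment counts
    # each individual at most once per SNP
    for s in rohset.segments:
        if s.population != population or s.chromosome not in chrom_index:
            continue
        j = chrom_index[s.chromosome]
        pos = pos_arr[j]
        lo = np.searchsorted(pos, s.start, side="left")
        hi = np.searchsorted(pos, s.end, side="right")
        count[j[lo:hi]] += 1
    return pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "incidence": count / len(members),
        }
    )


def island_threshold(track: pd.DataFrame, top_fraction: float = 0.01) -> float:
    """Incidence of the ``ceil(top_fraction * n)``-th most-covered SNP."""
    if len(track) == 0:
        raise ValueError("empty incidence track")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    inc = np.sort(track["incidence"].to_numpy())
    k = math.ceil(top_fraction * len(inc))
    thr = float(inc[len(inc) - k])
    if inc[0] == inc[-1]:
        warnings.warn("degenerate incidence track: all values equal", stacklevel=2)
    return thr


def call_islands(
    track: pd.DataFrame,
    threshold: float,
    population: str = "",
    max_gap_kb: float = 1000.0,
    min_snps: int = 2,
) -> list[ROHIsland]:
    """Maximal runs of >= ``min_snps`` adjacent SNPs with incidence >=
    threshold, broken at physical gaps > ``max_gap_kb``."""
    if not 0.0 <= threshold:
        raise ValueError("threshold must be non-negative")
    islands: list[ROHIsland] = []
    max_gap = max_gap_kb * 1000.0
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        inc = grp["incidence"].to_numpy()
        idx = np.nonzero(inc >= threshold)[0]
        if idx.size == 0:
            continue
        breaks = np.nonzero((np.diff(idx) > 1) | (np.diff(pos[idx]) > max_gap))[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(starts, ends):
            if b - a + 1 < min_snps:
                continue
            lo, hi = idx[a], idx[b]
            islands.append(
                ROHIsland(
                    chromosome=str(chrom),
                    start=int(pos[lo]),
                    end=int(pos[hi]),
                    n_snps=int(hi - lo + 1),
                    mean_incidence=float(inc[lo:hi + 1].mean()),
                    population=population,
                )
            )
    return islands


def intersect_intervals(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs (x in a, y in b) overlapping by >= 1 bp (half-open)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for y in b:
        by_chrom.setdefault(y.chrom, []).append(y)
    for ys in by_chrom.values():
        ys.sort(key=lambda y: y.start)
    out = []
    for x in a:
        ys = by_chrom.get(x.chrom, [])
        starts = [y.start for y in ys]
        # candidates: those starting before x.end
        hi = bisect.bisect_left(starts, x.end)
        for y in ys[:hi]:
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov > 0:
                out.append((x, y, ov))
    return out


def islands_to_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": i.population,
                "chrom": i.chromosome,
                "start": i.start,
                "end": i.end,
                "n_snps": i.n_snps,
                "mean_incidence": i.mean_incidence,
                "size_kb": (i.end - i.start + 1) / 1000.0,
            }
            for i in islands
        ],
        columns=["population", "chrom", "start", "end", "n_snps",
                 "mean_incidence", "size_kb"],
    )


def write_islands_bed(islands: list[ROHIsland], path) -> None:
    with open(path, "w") as fh:
        for i in islands:
            fh.write(f"{i.chromosome}\t{i.start - 1}\t{i.end}\t{i.population}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    """BED or 4+-column TSV (chrom, start, end, label...) -> intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            label = parts[3] if len(parts) > 3 else None
            meta = tuple(parts[4:]) if len(parts) > 4 else ()
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                label=label, metadata=meta)
            )
    return out


def overlap_report(
    pairs: list[tuple[GenomicInterval, GenomicInterval, int]],
    group_a: str = "a",
    group_b: str = "b",
) -> pd.DataFrame:
    rows = []
    for x, y, ov in pairs:
        rows.append(
            {
                "group_a": group_a,
                "group_b": group_b,
                "chrom": x.chrom,
                "a_start": x.start,
                "a_end": x.end,
                "b_start": y.start,
                "b_end": y.end,
                "overlap_bp": ov,
                "a_label": x.label or "",
                "b_label": y.label or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "chrom", "a_start", "a_end",
                 "b_start", "b_end", "overlap_bp", "a_label", "b_label"],
    )
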