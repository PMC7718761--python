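"""Core genotype containers.

Genotype calls are stored as a dense ``int8`` matrix of shape
(individuals, variants) with the coding

    0 = HOM_REF, 1 = HET, 2 = HOM_ALT, -1 = MISSING

i.e. the number of ALT alleles, with -1 for missing.  Variant metadata
lives in a plain :class:`pandas.DataFrame` with columns
``chrom, pos, id, ref, alt`` (``pos`` is 1-based and strictly increasing
within each chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


def make_variant_table(chrom, pos, ref=None, alt=None, ids=None) -> pd.DataFrame:
    """Assemble a variant table and validate its ordering invariant."""
    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "id": ids if ids is not None else ["."] * n,
            "ref": ref if ref is not None else ["A"] * n,
            "alt": alt if alt is not None else ["G"] * n,
        }
    )
    validate_variant_table(df)
    return df


def validate_variant_table(variants: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table lacks columns: {missing}")
    for chrom, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic calls for a multi-population cohort.

    Attributes
    ----------
    calls:
        ``int8`` array, shape (n_individuals, n_variants).
    samples:
        individual identifiers, one per row.
    populations:
        population label of each individual, aligned with ``samples``.
    """

    calls: np.ndarray
    samples: list[str]
    populations: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x variants)")
        if len(self.samples) != self.calls.shape[0]:
            raise ValueError("samples do not match call matrix rows")
        if len(self.populations) != self.calls.shape[0]:
            raise ValueError("every individual needs exactly one population")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_rows(self, population: str) -> np.ndarray:
        rows = np.array([i for i, p in enumerate(self.populations) if p == population])
        if rows.size == 0:
            raise ValueError(f"unknown or empty population: {population!r}")
        return rows

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[:, mask_or_index], list(self.samples), list(self.populations)
        )


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end), 0-based, for interchange.

    The half-open convention matches BED; detection-side segment
    coordinates (1-based inclusive SNP positions) are converted on export.
    """

    chrom: str
    start: int
    end: int
    label: str | None = None
    metadata: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty/negative interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))
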