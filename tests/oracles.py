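"""Independent brute-force oracles used to validate the implementations.

Everything here is written as plain Python loops over explicit
definitions, deliberately sharing no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

from rohscan.genotypes import HET, MISSING


def hwe_p_oracle(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Exact two-sided HWE p-value by full enumeration of heterozygote
    counts, using normalized factorial probabilities in rational
    arithmetic."""
    n = n_hom1 + n_het + n_hom2
    a_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    a_major = 2 * n - a_minor

    def prob(h: int) -> Fraction:
        hom_minor = (a_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_minor < 0 or hom_major < 0 or (a_minor - h) % 2:
            return Fraction(0)
        num = factorial(n) * 2**h * factorial(a_minor) * factorial(a_major)
        den = (
            factorial(hom_minor) * factorial(h) * factorial(hom_major)
            * factorial(2 * n)
        )
        return Fraction(num, den)

    masses = {h: prob(h) for h in range(a_minor % 2, a_minor + 1, 2)}
    total = sum(masses.values())
    obs = masses[n_het]
    return sum(m for m in masses.values() if m <= obs) / total


def roh_oracle(calls, positions, params) -> list[tuple[int, int, int]]:
    """ROH calls by direct per-window counting and run enumeration.

    Returns (start, end, n_snps) tuples.
    """
    calls = list(calls)
    positions = list(positions)
    n = len(calls)
    w = min(params.window_snps, n)

    win_ok = []
    for start in range(n - w + 1):
        het = sum(1 for c in calls[start:start + w] if c == HET)
        mis = sum(1 for c in calls[start:start + w] if c == MISSING)
        win_ok.append(het <= params.window_max_het and mis <= params.window_max_missing)

    flagged = []
    for i in range(n):
        lo = max(0, i - w + 1)
        hi = min(i, n - w)
        windows = win_ok[lo:hi + 1]
        rate = sum(windows) / len(windows)
        flagged.append(rate >= params.hit_proportion and calls[i] != HET)

    segs = []
    i = 0
    max_gap = params.max_gap_kb * 1000.0
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n and flagged[j + 1]
            and positions[j + 1] - positions[j] <= max_gap
        ):
            j += 1
        n_snps = j - i + 1
        length = positions[j] - positions[i] + 1
        if (
            n_snps >= params.min_snps
            and length >= params.min_length_kb * 1000.0
            and length / n_snps <= params.min_density_kb_per_snp * 1000.0
        ):
            segs.append((int(positions[i]), int(positions[j]), int(n_snps)))
        i = j + 1
    return segs


def incidence_oracle(segments, positions, members) -> list[float]:
    """Per-SNP incidence by O(SNPs x segments) containment checks;
    ``segments`` are (individual, start, end) on one chromosome."""
    out = []
    for p in positions:
        covered = {
            ind for ind, s, e in segments if s <= p <= e and ind in members
        }
        out.append(len(covered) / len(members))
    return out


def islands_oracle(positions, incidence, threshold, max_gap_bp, min_snps=2):
    """Island calls by direct run enumeration; returns (start, end, n)."""
    n = len(positions)
    out = []
    i = 0
    while i < n:
        if incidence[i] < threshold:
            i += 1
            continue
        j = i
        while (
            j + 1 < n and incidence[j + 1] >= threshold
            and positions[j + 1] - positions[j] <= max_gap_bp
        ):
            j += 1
        if j - i + 1 >= min_snps:
            out.append((int(positions[i]), int(positions[j]), j - i + 1))
        i = j + 1
    return out


def intersect_oracle(a, b):
    """All-pairs quadratic interval intersection (half-open)."""
    out = []
    for x in a:
        for y in b:
            if x.chrom != y.chrom:
                continue
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov > 0:
                out.append((x, y, ov))
    return out


def coverage_oracle(segments, chrom_length) -> int:
    """Covered bp on one chromosome for one individual via a bitmap."""
    covered = bytearray(chrom_length)
    for s, e in segments:  # 1-based inclusive
        for p in range(s - 1, e):
            covered[p] = 1
    return sum(covered)
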