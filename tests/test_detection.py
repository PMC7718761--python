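"""Sliding-window ROH caller: worked examples, oracle equivalence and
recovery of planted tracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rohscan
from oracles import roh_oracle
from rohscan.detection import ScanParams, call_roh, scan_cohort, window_hit_rates
from rohscan.genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

P = ScanParams()


def _pos(n, spacing=5000, start=10_000):
    return np.arange(start, start + n * spacing, spacing)


def test_all_homozygous_chromosome_has_rate_one():
    rates = window_hit_rates(np.zeros(100, dtype=np.int8), P)
    assert np.all(rates == 1.0)


def test_all_het_chromosome_has_rate_zero():
    rates = window_hit_rates(np.full(100, HET, dtype=np.int8), P)
    assert np.all(rates == 0.0)


def test_single_het_within_allowance_keeps_rate_one():
    calls = np.zeros(150, dtype=np.int8)
    calls[75] = HET
    assert np.all(window_hit_rates(calls, P) == 1.0)


def test_short_chromosome_is_one_whole_window():
    calls = np.zeros(30, dtype=np.int8)
    calls[:4] = HET  # 4 het > allowance of 3 in the single window
    assert np.all(window_hit_rates(calls, P) == 0.0)
    calls[:4] = 0
    calls[0] = HET
    assert np.all(window_hit_rates(calls, P) == 1.0)


def test_empty_calls_rejected():
    with pytest.raises(ValueError):
        window_hit_rates(np.array([], dtype=np.int8), P)


def test_minimal_segment_reported_with_snp_coordinates():
    # 60 HOM SNPs evenly spanning ~400 kb -> one segment
    pos = np.linspace(100_000, 500_000, 60).astype(np.int64)
    segs = call_roh(np.zeros(60, dtype=np.int8), pos, P)
    assert len(segs) == 1
    assert segs[0].start == pos[0] and segs[0].end == pos[-1]
    assert segs[0].n_snps == 60


def test_min_length_criterion_rejects_short_run():
    pos = np.linspace(100_000, 300_000, 60).astype(np.int64)  # 200 kb
    assert call_roh(np.zeros(60, dtype=np.int8), pos, P) == []


def test_min_snp_criterion_rejects_sparse_run():
    pos = np.linspace(100_000, 500_000, 40).astype(np.int64)  # 40 SNPs
    assert call_roh(np.zeros(40, dtype=np.int8), pos, P) == []


def test_large_gap_splits_run_in_two():
    pos1 = np.linspace(100_000, 450_000, 60).astype(np.int64)
    pos2 = np.linspace(2_000_000, 2_350_000, 60).astype(np.int64)  # 1.55 Mb gap
    pos = np.concatenate([pos1, pos2])
    segs = call_roh(np.zeros(120, dtype=np.int8), pos, P)
    assert len(segs) == 2
    assert segs[0].end == pos1[-1] and segs[1].start == pos2[0]


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        call_roh(np.zeros(10, dtype=np.int8), np.arange(9), P)


def _random_chromosome(rng, n):
    het = rng.uniform(0.0, 0.4)
    calls = rng.choice(
        [HOM_REF, HET, HOM_ALT, MISSING], size=n,
        p=[(1 - het) * 0.45, het, (1 - het) * 0.45, (1 - het) * 0.1],
    ).astype(np.int8)
    pos = np.cumsum(rng.integers(100, 20_000, size=n)) + 1
    # sprinkle occasional huge gaps to exercise the split rule
    gaps = rng.random(n) < 0.005
    pos = pos + np.cumsum(np.where(gaps, 2_000_000, 0))
    return calls, pos.astype(np.int64)


def test_caller_equals_bruteforce_oracle_on_random_chromosomes(rng):
    for _ in range(25):
        n = int(rng.integers(30, 1200))
        calls, pos = _random_chromosome(rng, n)
        got = [(s.start, s.end, s.n_snps) for s in call_roh(calls, pos, P)]
        assert got == roh_oracle(calls, pos, P)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_stricter_postfilters_never_add_segments(seed):
    rng = np.random.default_rng(seed)
    calls, pos = _random_chromosome(rng, 800)
    base = call_roh(calls, pos, P)
    for stricter in (
        dataclasses.replace(P, min_length_kb=600.0),
        dataclasses.replace(P, min_snps=80),
    ):
        out = call_roh(calls, pos, stricter)
        assert len(out) <= len(base)
        assert sum(s.length for s in out) <= sum(s.length for s in base)
        assert {(s.start, s.end) for s in out} <= {(s.start, s.end) for s in base}


def test_no_reported_segment_contains_an_oversized_gap(clean_cohort, clean_rohset):
    _, variants, _ = clean_cohort
    pos_by_chrom = {
        c: grp["pos"].to_numpy() for c, grp in variants.groupby("chrom", sort=False)
    }
    for s in clean_rohset.segments[:500]:
        pos = pos_by_chrom[s.chromosome]
        inside = pos[(pos >= s.start) & (pos <= s.end)]
        assert np.max(np.diff(inside)) <= P.max_gap_kb * 1000


def test_all_het_cohort_yields_no_segments():
    calls = np.full((4, 300), HET, dtype=np.int8)
    m = GenotypeMatrix(calls, [f"i{k}" for k in range(4)], ["P"] * 4)
    v = rohscan.make_variant_table(["chr1"] * 300, _pos(300))
    assert scan_cohort(m, v).segments == []


def test_scan_cohort_is_per_individual_composition(clean_cohort, clean_rohset):
    matrix, variants, _ = clean_cohort
    i = matrix.samples.index("WL_001")
    chrom_mask = variants["chrom"] == "chr2"
    segs = call_roh(
        matrix.calls[i, chrom_mask.to_numpy()],
        variants.loc[chrom_mask, "pos"].to_numpy(),
        P, individual="WL_001", population="WL", chromosome="chr2",
    )
    cohort_slice = [
        s for s in clean_rohset.segments
        if s.individual == "WL_001" and s.chromosome == "chr2"
    ]
    assert segs == cohort_slice


def test_planted_tracts_are_covered_by_detected_segments(clean_cohort, clean_rohset):
    """Error-free planted tracts >= 400 kb: a single detected run spans
    every SNP inside each truth tract (the run may additionally extend
    into flanking SNPs that are homozygous by chance, and the truth
    interval's bp boundaries can fall between SNPs, so the check is
    against the tract's SNP-observable span)."""
    _, variants, truth = clean_cohort
    pos_by_chrom = {
        c: grp["pos"].to_numpy() for c, grp in variants.groupby("chrom", sort=False)
    }
    by_ind = {}
    for s in clean_rohset.segments:
        by_ind.setdefault((s.individual, s.chromosome), []).append(s)
    n_checked = 0
    for t in truth:
        iv = t.interval
        if iv.length < 400_000:
            continue
        pos = pos_by_chrom[iv.chrom]
        inside = pos[(pos > iv.start) & (pos <= iv.end)]
        if len(inside) < 50:
            continue  # too sparse for the SNP-count criterion by chance
        n_checked += 1
        cands = by_ind.get((t.individual, iv.chrom), [])
        assert any(
            s.start <= inside[0] and s.end >= inside[-1] for s in cands
        ), (t.individual, iv)
    assert n_checked > 100
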