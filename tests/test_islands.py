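"""ROH islands: incidence, thresholding, calling and interval overlap."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rohscan
from oracles import incidence_oracle, intersect_oracle, islands_oracle
from rohscan.detection import ROHSegment, ROHSet, ScanParams
from rohscan.genotypes import GenomicInterval, make_variant_table
from rohscan.islands import (
    call_islands,
    intersect_intervals,
    island_threshold,
    snp_incidence,
)


def _variants(n, spacing=5000):
    return make_variant_table(["chr1"] * n, np.arange(1, n + 1) * spacing)


def _rohset(segments, individuals):
    return ROHSet(segments=segments, params=ScanParams(), individuals=individuals)


def test_incidence_zero_without_segments():
    rs = _rohset([], [("a", "P"), ("b", "P")])
    track = snp_incidence(rs, _variants(10), "P")
    assert (track["incidence"] == 0).all()


def test_incidence_one_when_every_individual_covered():
    inds = [(f"i{k}", "P") for k in range(5)]
    segs = [ROHSegment(f"i{k}", "P", "chr1", 10_000, 30_000, 5) for k in range(5)]
    track = snp_incidence(_rohset(segs, inds), _variants(10), "P")
    inside = (track["pos"] >= 10_000) & (track["pos"] <= 30_000)
    assert (track.loc[inside, "incidence"] == 1.0).all()
    assert (track.loc[~inside, "incidence"] == 0.0).all()


def test_incidence_matches_containment_oracle(rng):
    inds = [(f"i{k}", "P") for k in range(8)] + [("x", "Q")]
    segs = []
    for k in range(8):
        # disjoint random segments per individual
        cuts = np.sort(rng.choice(np.arange(1, 500_000, 1000), 8, replace=False))
        for s, e in zip(cuts[::2], cuts[1::2]):
            segs.append(ROHSegment(f"i{k}", "P", "chr1", int(s), int(e), 50))
    v = _variants(100, spacing=5000)
    track = snp_incidence(_rohset(segs, inds), v, "P")
    want = incidence_oracle(
        [(s.individual, s.start, s.end) for s in segs],
        v["pos"].tolist(),
        {f"i{k}" for k in range(8)},
    )
    assert track["incidence"].tolist() == pytest.approx(want)


def test_threshold_is_nearest_rank_order_statistic():
    track = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 101) * 1000,
         "incidence": np.arange(1, 101) / 100.0}
    )
    assert island_threshold(track, 0.01) == pytest.approx(1.00)
    assert island_threshold(track, 0.05) == pytest.approx(0.96)


def test_threshold_on_degenerate_track_warns():
    track = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 11) * 1000, "incidence": 0.0}
    )
    with pytest.warns(UserWarning, match="degenerate"):
        assert island_threshold(track, 0.01) == 0.0


def test_threshold_matches_sort_oracle(rng):
    inc = rng.integers(0, 26, size=10_000) / 25.0
    track = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 10_001) * 500, "incidence": inc}
    )
    got = island_threshold(track, 0.01)
    k = int(np.ceil(0.01 * len(inc)))
    want = sorted(inc, reverse=True)[k - 1]
    assert got == want


def test_island_called_over_uniform_background():
    inc = np.full(500, 0.4)
    inc[200:250] = 1.0
    track = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 501) * 5000, "incidence": inc}
    )
    found = call_islands(track, 0.96, population="P")
    assert len(found) == 1
    assert found[0].start == 201 * 5000 and found[0].end == 250 * 5000
    assert found[0].n_snps == 50
    assert found[0].mean_incidence == pytest.approx(1.0)


def test_impossible_threshold_yields_no_islands():
    track = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 101) * 1000, "incidence": 1.0}
    )
    assert call_islands(track, 1.01) == []


def test_single_snp_runs_discarded():
    inc = np.zeros(100)
    inc[50] = 1.0
    track = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 101) * 1000, "incidence": inc}
    )
    assert call_islands(track, 0.9) == []


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_islands_match_run_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 400
    pos = np.cumsum(rng.integers(1000, 400_000, size=n))
    inc = rng.integers(0, 11, size=n) / 10.0
    track = pd.DataFrame({"chrom": "chr1", "pos": pos, "incidence": inc})
    thr = 0.7
    got = [(i.start, i.end, i.n_snps) for i in call_islands(track, thr)]
    want = islands_oracle(pos, inc, thr, 1_000_000.0)
    assert got == want
    for isl in call_islands(track, thr):
        member = (pos >= isl.start) & (pos <= isl.end)
        assert (inc[member] >= thr).all()


def test_halfopen_interval_intersection():
    a = [GenomicInterval("c", 10, 20)]
    assert intersect_intervals(a, [GenomicInterval("c", 15, 25)])[0][2] == 5
    assert intersect_intervals(a, [GenomicInterval("c", 20, 30)]) == []


def test_intersection_matches_quadratic_oracle_and_is_symmetric(rng):
    def random_intervals(k):
        out = []
        for _ in range(k):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 1_000_000))
            out.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 50_000))))
        return out

    a, b = random_intervals(60), random_intervals(60)
    got = intersect_intervals(a, b)
    want = intersect_oracle(a, b)

    def key(t):
        return (t[0].chrom, t[0].start, t[0].end, t[1].start, t[1].end, t[2])

    assert sorted(got, key=key) == sorted(want, key=key)
    swapped = [(y, x, o) for x, y, o in intersect_intervals(b, a)]
    assert sorted(swapped, key=key) == sorted(got, key=key)


def test_shared_planted_region_is_the_unique_island():
    """A 1-Mb region autozygous in >= 90% of individuals is the single
    island at top_fraction 0.01 against <= 20% background incidence."""
    layout = rohscan.GenomeLayout(
        chromosomes=(("chr1", 50_000_000), ("chr2", 20_000_000)),
        snp_density=1 / 5000,
    )
    bins = rohscan.LENGTH_CLASS_BINS_MB
    profile = rohscan.PopulationProfile(
        "P", 30, 0.28, tract_length_distribution=((bins[0], 2.0),)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, variants, _ = rohscan.simulate_cohort(layout, [profile], seed=21)
    # plant the shared region directly: 28/30 individuals homozygous
    region = (10_000_000, 11_000_000)
    pos = variants["pos"].to_numpy()
    on_chr1 = variants["chrom"].to_numpy() == "chr1"
    inside = on_chr1 & (pos > region[0]) & (pos <= region[1])
    matrix.calls[:28, inside] = 0
    rohset = rohscan.scan_cohort(matrix, variants)
    track = snp_incidence(rohset, variants, "P")
    thr = island_threshold(track, 0.01)
    found = call_islands(track, thr, population="P")
    assert len(found) == 1
    isl = found[0]
    assert isl.chromosome == "chr1"
    assert abs(isl.start - region[0]) < 50_000
    assert abs(isl.end - region[1]) < 50_000
    assert isl.mean_incidence >= 0.9
    # background stays low
    outside = track.loc[~inside]
    assert outside.loc[outside["chrom"] == "chr2", "incidence"].max() <= 0.5
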