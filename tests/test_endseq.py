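"""End assignment, extent estimation, heatmaps and genotype comparison."""

import numpy as np
import pandas as pd
import pytest

from dsbscreen.endseq import (
    AssignedEnds,
    CutSite,
    EndAlignment,
    assign_ends,
    build_profiles,
    compare_genotypes,
    heatmap_matrix,
    read_ends_bed,
    read_sites_bed,
    resection_extent,
    write_ends_bed,
    write_sites_bed,
)

from helpers import oracle_assign


def test_assignment_distance_and_side():
    sites = [CutSite("chr1", 10_000, "s1")]
    ends = [EndAlignment("chr1", 10_300, "+")]
    a = assign_ends(ends, sites, window=5000)
    assert a.by_site["s1"] == [(300, "right")]
    a2 = assign_ends([EndAlignment("chr1", 9_700, "-")], sites, window=5000)
    assert a2.by_site["s1"] == [(-300, "left")]


def test_window_is_half_open():
    sites = [CutSite("chr1", 10_000, "s1")]
    inside = EndAlignment("chr1", 10_000 - 5000, "-")   # distance -5000: in
    outside = EndAlignment("chr1", 10_000 + 5000, "+")  # distance +5000: out
    far = EndAlignment("chr1", 15_001, "+")             # distance 5001: out
    a = assign_ends([inside, outside, far], sites, window=5000)
    assert len(a.by_site["s1"]) == 1 and a.unassigned == 2


def test_overlapping_windows_rejected():
    sites = [CutSite("chr1", 10_000, "s1"), CutSite("chr1", 15_000, "s2")]
    with pytest.raises(ValueError, match="s1.*s2"):
        assign_ends([], sites, window=5000)
    # same coordinates on different chromosomes are fine
    ok = [CutSite("chr1", 10_000, "s1"), CutSite("chr2", 10_000, "s2")]
    assign_ends([], ok, window=5000)


def test_assignment_matches_bruteforce_oracle(rng):
    """1,000 random ends around 20 sites agree with the all-pairs scan."""
    window = 1000
    sites = [
        CutSite(f"chr{1 + i % 3}", 5_000 + (i // 3) * 2500, f"site{i:02d}")
        for i in range(20)
    ]
    ends = [
        EndAlignment(
            f"chr{rng.integers(1, 5)}",
            int(rng.integers(0, 25_000)),
            "+" if rng.uniform() < 0.5 else "-",
        )
        for _ in range(1000)
    ]
    got = assign_ends(ends, sites, window=window)
    exp_by_site, exp_unassigned = oracle_assign(ends, sites, window)
    assert got.unassigned == exp_unassigned
    for sid in exp_by_site:
        assert sorted(got.by_site[sid]) == sorted(exp_by_site[sid])
    assert got.n_assigned + got.unassigned == len(ends)


def test_extent_bounded_by_support():
    assert resection_extent([3, -7, 10, 2, -1] * 20, quantile=0.99) <= 10


def test_extent_of_uniform_tracts_matches_order_statistic(rng):
    d = rng.uniform(0, 2000, size=1000)
    est = resection_extent(d, quantile=0.95)
    assert est == pytest.approx(0.95 * 2000, abs=50)


def test_extent_undefined_below_min_support():
    assert np.isnan(resection_extent([10, 20, 30], min_support=5))
    assert resection_extent([10, 20, 30], min_support=3) == pytest.approx(28, abs=3)


def test_extent_monotone_in_quantile(rng):
    d = rng.exponential(500, size=400)
    qs = np.linspace(0.1, 1.0, 10)
    ests = [resection_extent(d, quantile=q) for q in qs]
    assert all(a <= b for a, b in zip(ests, ests[1:]))


def test_extent_scales_exactly_with_distances(rng):
    d = rng.integers(0, 1500, size=200)
    assert resection_extent(2 * d) == 2 * resection_extent(d)


def _assigned_from(dist_side: dict[str, list[tuple[int, str]]], window=1000):
    return AssignedEnds(by_site=dist_side, unassigned=0, window=window)


def test_profiles_conserve_per_side_counts():
    a = _assigned_from(
        {"s1": [(10, "right"), (980, "right"), (-40, "left")], "s2": []}
    )
    profs = build_profiles(a, bin_size=25, min_support=1)
    p1 = {p.site_id: p for p in profs}["s1"]
    assert p1.signal[1].sum() == 2 and p1.signal[0].sum() == 1  # right, left
    assert p1.n_ends == 3
    assert p1.signal.shape == (2, 80)


def test_mirroring_swaps_left_and_right_extents(rng):
    cut = 50_000
    dists = rng.integers(0, 1800, size=60)
    sides = rng.uniform(size=60) < 0.5
    ends = [
        EndAlignment("c", cut + (d if r else -d), "+" if r else "-")
        for d, r in zip(dists, sides)
    ]
    mirrored = [
        EndAlignment("c", 2 * cut - e.end_position, "-" if e.strand == "+" else "+")
        for e in ends
    ]
    site = [CutSite("c", cut, "s")]
    p = build_profiles(assign_ends(ends, site, 2000), min_support=1, bin_size=25)[0]
    q = build_profiles(assign_ends(mirrored, site, 2000), min_support=1, bin_size=25)[0]
    assert p.extent_left == q.extent_right and p.extent_right == q.extent_left


def test_heatmap_dimensions_and_row_sums():
    rng = np.random.default_rng(5)
    by_site = {
        f"s{i}": [
            (int(rng.integers(-999, 999)), "right" if rng.uniform() < 0.5 else "left")
            for _ in range(int(rng.integers(5, 40)))
        ]
        for i in range(10)
    }
    a = _assigned_from(by_site, window=1000)
    profs = build_profiles(a, bin_size=25, min_support=1)
    mat = heatmap_matrix(profs, normalize="raw")
    assert mat.shape == (10, 2 * 1000 // 25)
    per_site = {p.site_id: p.n_ends for p in profs}
    for sid, row in mat.iterrows():
        assert row.sum() == per_site[sid]
    # rows sorted by descending total signal
    totals = mat.sum(axis=1).to_numpy()
    assert all(a >= b for a, b in zip(totals, totals[1:]))


def test_heatmap_per_million_sums_to_a_million():
    a = _assigned_from({"s1": [(1, "right")] * 30, "s2": [(-5, "left")] * 10})
    profs = build_profiles(a, bin_size=25, min_support=1)
    mat = heatmap_matrix(profs, normalize="per_million")
    assert mat.to_numpy().sum() == pytest.approx(1e6)


def test_protected_signal_stays_near_the_cut():
    a = _assigned_from({"s1": [(d, "right") for d in range(0, 150, 5)]})
    mat = heatmap_matrix(build_profiles(a, bin_size=25, min_support=1))
    cols = mat.columns.to_numpy()
    assert mat.loc[:, cols >= 200].to_numpy().sum() == 0


def test_heatmap_rejects_mixed_parameters():
    a1 = _assigned_from({"s1": [(1, "right")] * 6}, window=1000)
    a2 = _assigned_from({"s2": [(1, "right")] * 6}, window=2000)
    p1 = build_profiles(a1, bin_size=25)
    p2 = build_profiles(a2, bin_size=25)
    with pytest.raises(ValueError, match="window/bin"):
        heatmap_matrix(p1 + p2)


def test_heatmap_is_sufficient_for_n_ends():
    """Per-site totals are recomputable from the raw matrix alone."""
    a = _assigned_from({"s1": [(40, "right")] * 12, "s2": [(-700, "left")] * 7})
    profs = build_profiles(a, bin_size=25, min_support=1)
    mat = heatmap_matrix(profs, normalize="raw")
    recovered = mat.sum(axis=1).to_dict()
    assert recovered == {p.site_id: p.n_ends for p in profs}


def test_compare_identical_genotypes_gives_zero_deltas():
    a = _assigned_from({"s1": [(100, "right")] * 20, "s2": [(-900, "left")] * 20})
    profs = build_profiles(a, bin_size=25)
    table, summary = compare_genotypes(profs, profs)
    assert (table["delta_extent"] == 0).all()
    assert summary["median_delta"] == 0


def test_compare_rejects_site_mismatch():
    a = _assigned_from({"s1": [(100, "right")] * 20})
    b = _assigned_from({"s2": [(100, "right")] * 20})
    with pytest.raises(ValueError, match="site sets differ"):
        compare_genotypes(build_profiles(a), build_profiles(b))


def test_doubling_distances_doubles_every_extent():
    by_site = {"s1": [(d, "right") for d in (10, 60, 200, 500, 900)]}
    doubled = {"s1": [(2 * d, s) for d, s in by_site["s1"]]}
    pa = build_profiles(_assigned_from(by_site, window=2000), bin_size=25)
    pb = build_profiles(_assigned_from(doubled, window=2000), bin_size=25)
    table, _ = compare_genotypes(pa, pb)
    assert table.loc["s1", "extent_b"] == 2 * table.loc["s1", "extent_a"]


def test_bed_round_trip(tmp_path):
    sites = [CutSite("chr1", 10_000, "s1"), CutSite("chr2", 44_000, "s2")]
    ends = [EndAlignment("chr1", 10_250, "+"), EndAlignment("chr2", 43_900, "-")]
    write_sites_bed(sites, tmp_path / "sites.bed")
    write_ends_bed(ends, tmp_path / "ends.bed")
    assert read_sites_bed(tmp_path / "sites.bed") == sites
    assert read_ends_bed(tmp_path / "ends.bed") == ends
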