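"""Sliding-window smoothing, region detection, correlations, heatmaps."""

import numpy as np
import pytest

from genescape.catalog import ReferenceOrder
from genescape.errors import ConfigError, UndefinedValueError
from genescape.landscape import (
    LandscapeTrack,
    WindowSpec,
    detect_regions,
    heatmap_matrix,
    regions_to_bed,
    sliding_window,
    track_correlation,
)

from oracles import brute_window_means


def make_order(n, chrom_sizes=None):
    if chrom_sizes is None:
        chrom_sizes = [n]
    chroms, positions = [], []
    for ci, size in enumerate(chrom_sizes):
        chroms += [f"chr{ci + 1}"] * size
        positions += [(i + 1) * 100 for i in range(size)]
    return ReferenceOrder("ref", [f"G{i}" for i in range(n)], chroms, positions)


class TestSlidingWindow:
    def test_constant_track_is_unchanged(self):
        out = sliding_window(np.full(300, 0.86), WindowSpec(size=101))
        assert np.allclose(out, 0.86)

    def test_matches_bruteforce_with_missing(self):
        rng = np.random.default_rng(7)
        raw = rng.random(400)
        raw[rng.random(400) < 0.1] = np.nan
        out = sliding_window(raw, WindowSpec(size=101))
        expected = brute_window_means(raw, 101)
        assert np.allclose(out, expected, equal_nan=True)

    def test_truncated_edge_is_mean_of_first_51(self):
        rng = np.random.default_rng(8)
        raw = rng.random(200)
        out = sliding_window(raw, WindowSpec(size=101))
        assert out[0] == pytest.approx(raw[:51].mean())

    def test_drop_edge_policy_leaves_edges_missing(self):
        out = sliding_window(np.ones(200), WindowSpec(size=101, edge_policy="drop"))
        assert np.isnan(out[:50]).all() and np.isnan(out[-50:]).all()
        assert np.allclose(out[50:-50], 1.0)

    def test_size_one_is_identity(self):
        raw = np.array([1.0, np.nan, 3.0])
        out = sliding_window(raw, WindowSpec(size=1))
        assert np.allclose(out, raw, equal_nan=True)

    def test_min_valid_fraction_gates_sparse_windows(self):
        raw = np.array([1.0, np.nan, np.nan, np.nan, 5.0])
        out = sliding_window(raw, WindowSpec(size=5, min_valid_fraction=0.5))
        assert np.isnan(out[2])  # only 2/5 valid
        out_loose = sliding_window(raw, WindowSpec(size=5, min_valid_fraction=0.2))
        assert out_loose[2] == pytest.approx(3.0)

    def test_per_chromosome_clipping(self):
        raw = np.concatenate([np.zeros(50), np.ones(50)])
        bounds = [("chr1", 0, 50), ("chr2", 50, 100)]
        clipped = sliding_window(raw, WindowSpec(size=21, span_chromosomes=False), bounds)
        assert np.allclose(clipped[:50], 0.0) and np.allclose(clipped[50:], 1.0)
        spanning = sliding_window(raw, WindowSpec(size=21))
        assert 0 < spanning[49] < 1

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            WindowSpec(size=100)

    def test_all_missing_rejected(self):
        with pytest.raises(UndefinedValueError):
            sliding_window(np.full(10, np.nan), WindowSpec(size=3))


class TestDetectRegions:
    def test_single_run(self):
        sm = np.array([0.9] * 10 + [0.5] * 5 + [0.9] * 10)
        (reg,) = detect_regions(sm, 0.70, "below", gap_max=0, min_width=1)
        assert (reg.start_rank, reg.end_rank) == (10, 15)
        assert reg.extreme == pytest.approx(0.5) and reg.n_windows == 5

    def test_gap_merging(self):
        sm = np.array([0.5] * 6 + [0.9] * 3 + [0.5] * 6)
        (reg,) = detect_regions(sm, 0.70, "below", gap_max=5, min_width=1)
        assert (reg.start_rank, reg.end_rank) == (0, 15)
        two = detect_regions(sm, 0.70, "below", gap_max=2, min_width=1)
        assert len(two) == 2

    def test_nothing_beyond_threshold(self):
        assert detect_regions(np.full(50, 0.9), 0.70, "below") == []

    def test_min_width_filter(self):
        sm = np.array([0.9] * 10 + [0.5] * 3 + [0.9] * 10)
        assert detect_regions(sm, 0.70, "below", gap_max=0, min_width=5) == []

    def test_below_and_above_partition_disjointly(self):
        rng = np.random.default_rng(9)
        sm = rng.random(300)
        t = 0.5
        below = detect_regions(sm, t, "below", gap_max=0, min_width=1)
        above = detect_regions(sm, t, "above", gap_max=0, min_width=1)
        covered_b = {r for reg in below for r in range(reg.start_rank, reg.end_rank)}
        covered_a = {r for reg in above for r in range(reg.start_rank, reg.end_rank)}
        assert not covered_b & covered_a

    def test_refinement_trims_boxcar_ramp(self):
        # a planted deep plateau surrounded by linear ramps: refinement should
        # pull the edges toward the plateau
        sm = np.concatenate(
            [np.full(50, 0.9), np.linspace(0.9, 0.4, 20), np.full(30, 0.4),
             np.linspace(0.4, 0.9, 20), np.full(50, 0.9)]
        )
        (coarse,) = detect_regions(sm, 0.8, "below", gap_max=0, min_width=1)
        (fine,) = detect_regions(sm, 0.8, "below", gap_max=0, min_width=1, refine_fraction=0.6)
        assert coarse.start_rank < fine.start_rank and fine.end_rank < coarse.end_rank


class TestCorrelationAndHeatmap:
    def test_affine_relation_is_perfect(self):
        a = np.random.default_rng(1).random(100)
        assert track_correlation(a, 2 * a + 1) == pytest.approx(1.0)
        assert track_correlation(a, -a) == pytest.approx(-1.0)

    def test_degenerate_inputs_signalled(self):
        with pytest.raises(UndefinedValueError):
            track_correlation(np.ones(10), np.arange(10.0))
        with pytest.raises(UndefinedValueError):
            track_correlation(np.array([1.0, np.nan]), np.array([2.0, np.nan]))

    def test_single_track_heatmap_equals_smoothed(self):
        order = make_order(20)
        raw = np.arange(20.0)
        tr = LandscapeTrack(order, raw, raw, "t", WindowSpec(size=1))
        hm = heatmap_matrix([tr])
        assert hm.shape == (1, 20) and np.allclose(hm.values[0], raw)

    def test_mixed_orders_rejected(self):
        t1 = LandscapeTrack(make_order(10), np.ones(10), np.ones(10), "a")
        t2 = LandscapeTrack(make_order(12), np.ones(12), np.ones(12), "b")
        with pytest.raises(ConfigError):
            heatmap_matrix([t1, t2])


class TestRegionsToBed:
    def test_region_split_at_chromosome_bounds(self):
        order = make_order(20, [10, 10])
        regions = detect_regions(
            np.array([0.9] * 5 + [0.5] * 10 + [0.9] * 5), 0.7, "below", 0, 1
        )
        bed = regions_to_bed(regions, order)
        assert list(bed["chrom"]) == ["chr1", "chr2"]
        # genomic coordinates from the order's positions (half-open)
        assert bed.iloc[0]["start"] == 600 and bed.iloc[0]["end"] == 1001
        assert (bed["score"] == 500).all()
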