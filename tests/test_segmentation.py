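"""Kernel cost, binary segmentation, elbow selection and circular
segment statistics, checked against brute-force and exhaustive oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divecorrect.config import AnalysisConfig
from divecorrect.segmentation import (
    annotate_shallow,
    binary_segmentation,
    circular_mean,
    circular_rmse,
    heading_changes,
    heading_series,
    kernel_cost,
    median_heuristic_gamma,
    segment_headings,
    segment_stats,
    select_nbkps,
    wrap_angle,
)
from divecorrect.types import BathymetryGrid, Segment


def embed(headings_deg):
    th = np.radians(np.asarray(headings_deg, dtype=float))
    return np.column_stack([np.cos(th), np.sin(th)])


def brute_force_cost(x, gamma):
    """Independent double-sum evaluation of the kernel segment cost."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    total = 0.0
    for i in range(n):
        for j in range(n):
            d2 = float(np.sum((x[i] - x[j]) ** 2))
            total += np.exp(-gamma * d2)
    return n - total / n


class TestHeadingSeries:
    def test_constant_90_maps_to_0_1(self):
        h, emb, carried = heading_series([1.0, 1.0], [0.0, 0.0])
        assert np.allclose(h, 90.0)
        assert np.allclose(emb, [[0.0, 1.0], [0.0, 1.0]], atol=1e-15)

    def test_wraparound_is_continuous(self):
        _, emb, _ = heading_series(
            [np.sin(np.radians(359)), np.sin(np.radians(1))],
            [np.cos(np.radians(359)), np.cos(np.radians(1))],
        )
        assert np.linalg.norm(emb[0] - emb[1]) < 0.05

    def test_antipodal_headings(self):
        _, emb, _ = heading_series([0.0, 0.0], [1.0, -1.0])
        assert np.allclose(emb[0], -emb[1])

    def test_zero_speed_carries_previous(self):
        h, _, carried = heading_series([1.0, 0.0, 1.0], [0.0, 0.0, 0.0])
        assert h[1] == 90.0
        assert carried.tolist() == [False, True, False]

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            heading_series([0.0, 0.0], [0.0, 0.0])


class TestKernelCost:
    def test_identical_points_zero(self):
        x = np.tile([[0.3, 0.4]], (10, 1))
        assert kernel_cost(x, gamma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_points_closed_form(self):
        x = np.array([[0.0, 0.0], [0.3, 0.4]])  # distance 0.5
        gamma = 2.0
        expected = 1.0 - np.exp(-gamma * 0.25)
        assert kernel_cost(x, gamma) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        x = embed(rng.uniform(0, 360, n))
        gamma = float(rng.uniform(0.1, 5.0))
        assert kernel_cost(x, gamma) == pytest.approx(brute_force_cost(x, gamma), abs=1e-10)


def exhaustive_best_splits(x, gamma, n_bkps, min_size):
    """Exhaustive minimum-cost segmentation with n_bkps breakpoints."""
    n = len(x)
    best = None
    for combo in itertools.combinations(range(min_size, n - min_size + 1), n_bkps):
        if any(b - a < min_size for a, b in zip(combo[:-1], combo[1:])):
            continue
        edges = [0, *combo, n]
        cost = sum(kernel_cost(x[a:b], gamma) for a, b in zip(edges[:-1], edges[1:]))
        if best is None or cost < best[0]:
            best = (cost, list(combo))
    return best


class TestBinarySegmentation:
    def test_constant_series_negligible_gains(self):
        x = embed(np.full(40, 10.0))
        path, costs = binary_segmentation(x, 3, min_size=5, gamma=1.0)
        assert costs[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.abs(np.diff(costs)) < 1e-12)

    def test_single_change_recovered_within_2_days(self):
        rng = np.random.default_rng(12)
        h = np.concatenate([np.zeros(100), np.full(100, 45.0)]) + rng.normal(0, 5, 200)
        x = embed(h)
        path, costs = binary_segmentation(x, 2, min_size=5)
        assert abs(path[1][0] - 100) <= 2

    def test_single_split_equals_exhaustive(self):
        rng = np.random.default_rng(3)
        h = np.concatenate([rng.normal(0, 8, 30), rng.normal(50, 8, 25)])
        x = embed(h)
        gamma = median_heuristic_gamma(x)
        path, costs = binary_segmentation(x, 1, min_size=5, gamma=gamma)
        _, best = exhaustive_best_splits(x, gamma, 1, 5)
        assert path[1] == best

    def test_two_changes_within_5pct_of_exhaustive(self):
        rng = np.random.default_rng(4)
        h = np.concatenate(
            [rng.normal(0, 5, 20), rng.normal(45, 5, 20), rng.normal(-10, 5, 20)]
        )
        x = embed(h)
        gamma = median_heuristic_gamma(x)
        path, costs = binary_segmentation(x, 2, min_size=5, gamma=gamma)
        best_cost, best_bkps = exhaustive_best_splits(x, gamma, 2, 5)
        assert costs[2] <= best_cost * 1.05 + 1e-9
        assert all(abs(a - b) <= 3 for a, b in zip(path[2], best_bkps))

    def test_cost_curve_non_increasing(self):
        rng = np.random.default_rng(6)
        x = embed(rng.uniform(0, 360, 80))
        _, costs = binary_segmentation(x, 6, min_size=5)
        assert np.all(np.diff(costs) <= 1e-12)

    def test_too_short_series_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            binary_segmentation(embed(np.zeros(8)), 1, min_size=5)


class TestSelectNbkps:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([100.0, 40.0, 35.0, 33.0], 1),
            ([100.0, 80.0, 30.0, 28.0], 2),
        ],
    )
    def test_elbow_rule(self, curve, expected):
        n, warn = select_nbkps(curve)
        assert n == expected
        assert not warn

    def test_flat_curve_warns_returns_1(self):
        n, warn = select_nbkps([5.0, 5.0, 5.0])
        assert n == 1
        assert warn

    def test_tie_prefers_smallest_n(self):
        n, _ = select_nbkps([100.0, 60.0, 20.0, 19.0])  # drops 40, 40, 1
        assert n == 1


class TestCircularStats:
    def test_constant_heading_rmse_zero_valid(self):
        segs = segment_stats(np.full(12, 123.0), [])
        assert segs[0].rmse == pytest.approx(0.0, abs=1e-9)
        assert segs[0].valid
        assert segs[0].theta_bar == pytest.approx(123.0)

    def test_wrap_safe_mean_and_rmse(self):
        h = np.array([350.0, 10.0] * 10)
        segs = segment_stats(h, [])
        assert segs[0].theta_bar == pytest.approx(0.0, abs=1e-9)
        assert segs[0].rmse == pytest.approx(10.0, abs=1e-9)

    def test_rmse_35_invalid(self):
        h = np.array([325.0, 35.0] * 10)
        segs = segment_stats(h, [])
        assert segs[0].rmse == pytest.approx(35.0, abs=1e-9)
        assert not segs[0].valid

    @given(st.floats(min_value=-720, max_value=720))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_rotation_invariance(self, shift):
        h = np.array([10.0, 20.0, 350.0, 5.0, 15.0])
        base = segment_stats(h, [])[0]
        rot = segment_stats((h + shift) % 360.0, [])[0]
        assert rot.rmse == pytest.approx(base.rmse, abs=1e-8)
        assert wrap_angle(rot.theta_bar - base.theta_bar - shift) == pytest.approx(0.0, abs=1e-8)


class TestHeadingChanges:
    def _seg(self, theta, valid=True):
        return Segment(start=0, end=1, theta_bar=theta, rmse=0.0, valid=valid)

    def test_wraps_to_signed_interval(self):
        deltas = heading_changes([self._seg(20.0), self._seg(340.0)])
        assert deltas == [pytest.approx(-40.0)]

    def test_zero_change(self):
        assert heading_changes([self._seg(10.0), self._seg(10.0)]) == [pytest.approx(0.0)]

    def test_invalid_segment_skipped(self):
        segs = [self._seg(10.0), self._seg(200.0, valid=False), self._seg(30.0)]
        deltas = heading_changes(segs)
        assert deltas == [pytest.approx(20.0)]

    def test_fewer_than_two_valid_empty(self):
        assert heading_changes([self._seg(10.0), self._seg(50.0, valid=False)]) == []


class TestAnnotateShallow:
    def _bathy(self):
        lats = np.arange(-10.0, 1.0, 1.0)
        lons = np.arange(50.0, 61.0, 1.0)
        depth = np.full((len(lats), len(lons)), 4000.0)
        depth[lats >= -2.0, :] = 150.0
        return BathymetryGrid(lats=lats, lons=lons, depth_m=depth)

    def test_breakpoint_and_segment_flags(self):
        lons = np.full(10, 55.0)
        lats = np.linspace(-8.0, -0.5, 10)  # last days over the 150 m shelf
        segs = [Segment(0, 5, 0.0, 0.0, True), Segment(5, 10, 0.0, 0.0, True)]
        flags = annotate_shallow(segs, [5], lons, lats, self._bathy())
        assert flags == [False]
        assert segs[0].shallow is False
        seg_shelf = [Segment(8, 10, 0.0, 0.0, True)]
        annotate_shallow(seg_shelf, [8], lons, lats, self._bathy())
        assert seg_shelf[0].shallow is True

    def test_off_grid_flag_missing(self):
        segs = [Segment(0, 2, 0.0, 0.0, True)]
        flags = annotate_shallow(segs, [1], np.array([55.0, 120.0]), np.array([-5.0, -5.0]),
                                 self._bathy())
        assert flags == [None]
        assert segs[0].shallow is None


class TestSegmentHeadings:
    def test_two_leg_series_end_to_end(self):
        rng = np.random.default_rng(9)
        h = np.concatenate([np.zeros(40), np.full(40, 40.0)]) + rng.normal(0, 6, 80)
        u = np.sin(np.radians(h)) * 0.5
        v = np.cos(np.radians(h)) * 0.5
        res = segment_headings(u, v)
        assert res.n_bkps == 1
        assert abs(res.breakpoints[0] - 40) <= 2
        assert res.segments[0].theta_bar == pytest.approx(0.0, abs=3.0) or \
            res.segments[0].theta_bar == pytest.approx(360.0, abs=3.0)
        assert res.segments[1].theta_bar == pytest.approx(40.0, abs=3.0)
        deltas = [s.delta_theta for s in res.segments if s.delta_theta is not None]
        assert deltas[0] == pytest.approx(40.0, abs=5.0)
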