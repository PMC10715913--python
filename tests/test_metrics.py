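"""Straightness, speed summaries, the latitude-banded error profile and
paired variant comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divecorrect.metrics import (
    compare_tracks,
    constant_heading_share,
    latitudinal_error_profile,
    per_track_report,
    speed_summary,
    straightness,
)
from divecorrect.types import Segment


class TestStraightness:
    def test_straight_track_is_one(self):
        lats = np.linspace(-15.0, -14.0, 11)
        lons = np.full(11, 55.0)
        assert straightness(lons, lats) == pytest.approx(1.0, abs=1e-9)

    def test_right_angle_is_sqrt2_over_2(self):
        """Two equal legs at 90 degrees: net/path = sqrt(2)/2."""
        lons = [55.0, 55.0, 55.1]
        lats = [0.0, 0.1, 0.1]
        # legs ~11.1 km each; ellipsoidal lon/lat degree lengths differ
        assert straightness(lons, lats) == pytest.approx(np.sqrt(2) / 2, abs=2e-3)

    def test_closed_loop_is_zero(self):
        lons = [55.0, 55.1, 55.1, 55.0, 55.0]
        lats = [0.0, 0.0, 0.1, 0.1, 0.0]
        assert straightness(lons, lats) == pytest.approx(0.0, abs=1e-12)

    def test_zero_path_undefined(self):
        assert np.isnan(straightness([55.0, 55.0], [0.0, 0.0]))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        steps = rng.normal(0, 0.05, (12, 2))
        base = np.cumsum(steps, axis=0)
        s0 = straightness(55 + base[:, 0], base[:, 1])
        ang = np.radians(33.0)
        rot = base @ np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]).T
        s1 = straightness(55 + rot[:, 0], rot[:, 1])
        # degree-space rotation is only approximately a metric rotation
        assert s1 == pytest.approx(s0, rel=5e-3)


class TestSpeedSummary:
    def _kin(self, speeds):
        return pd.DataFrame(
            {"ustad": speeds, "vstad": np.zeros(len(speeds)),
             "us0": speeds, "vs0": np.zeros(len(speeds))}
        )

    def test_constant_speed(self):
        s = speed_summary(self._kin([0.5] * 6))
        assert (s["mean"], s["sd"], s["max"], s["exceedance"]) == (0.5, 0.0, 0.5, 0.0)

    def test_mixed_speeds_and_exceedance(self):
        s = speed_summary(self._kin([0.4, 0.6, 1.0]))
        assert s["mean"] == pytest.approx(2.0 / 3.0)
        assert s["max"] == 1.0
        assert s["exceedance"] == pytest.approx(1.0 / 3.0)

    def test_brute_force_recomputation(self):
        rng = np.random.default_rng(8)
        u, v = rng.normal(0, 0.3, 50), rng.normal(0, 0.3, 50)
        kin = pd.DataFrame({"ustad": u, "vstad": v, "us0": u, "vs0": v})
        s = speed_summary(kin)
        sp = np.sqrt(u**2 + v**2)
        assert s["mean"] == pytest.approx(sp.sum() / 50, abs=1e-12)
        assert s["sd"] == pytest.approx(np.sqrt(((sp - sp.mean()) ** 2).sum() / 49), abs=1e-12)

    def test_empty_row_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="divecorrect"):
            s = speed_summary(self._kin([np.nan, np.nan]))
        assert s["n"] == 0
        assert np.isnan(s["mean"])


class TestLatitudinalProfile:
    def test_bands_and_benchmark(self):
        kin = pd.DataFrame(
            {
                "lat12": [-12.3, -12.6, -3.2, -3.8, -3.5],
                "eps": [0.004, 0.006, 0.5, 0.7, np.nan],
            }
        )
        prof = latitudinal_error_profile(kin)
        low = prof[prof["lat_low"] == -13.0].iloc[0]
        high = prof[prof["lat_low"] == -4.0].iloc[0]
        assert low["mean_eps"] == pytest.approx(0.005)
        assert not low["above_benchmark"]
        assert high["n"] == 2  # the nan day is excluded
        assert high["above_benchmark"]

    def test_single_day_band_sd_zero(self):
        kin = pd.DataFrame({"lat12": [-7.5], "eps": [0.02]})
        prof = latitudinal_error_profile(kin)
        assert prof["sd_eps"].iloc[0] == 0.0


def make_segment(s_tad, s_surf, s_real, r_tad=10.0, r_surf=12.0, r_real=20.0, valid=True):
    seg = Segment(start=0, end=10, theta_bar=0.0, rmse=5.0, valid=valid)
    seg.straightness = {"tad": s_tad, "surface": s_surf, "real": s_real}
    seg.mean_rmse = {"tad": r_tad, "surface": r_surf, "real": r_real}
    return seg


class TestCompareTracks:
    def test_identical_metrics_t0_p1(self):
        segs = [make_segment(0.9, 0.9, 0.9) for _ in range(5)]
        out = compare_tracks(segs)
        t = out["tests"]["S_tad_vs_surface"]
        assert t["t"] == 0.0
        assert t["p"] == 1.0

    def test_constant_difference_significant(self):
        """Constant positive difference with tiny noise: p from the
        paired-t reference distribution is well below 0.05."""
        rng = np.random.default_rng(11)
        segs = []
        diffs = []
        for _ in range(8):
            s_real = 0.80 + rng.normal(0, 0.002)
            s_tad = s_real + 0.10 + rng.normal(0, 0.002)
            segs.append(make_segment(s_tad, 0.9, s_real))
            diffs.append(s_tad - s_real)
        out = compare_tracks(segs)
        got = out["tests"]["S_tad_vs_real"]
        # independent recomputation from the t CDF
        d = np.asarray(diffs)
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * (1 - stats.t.cdf(abs(t_oracle), len(d) - 1))
        assert got["t"] == pytest.approx(t_oracle, rel=1e-9)
        assert got["p"] == pytest.approx(p_oracle, abs=1e-12)
        assert got["p"] < 0.05

    def test_two_segments_low_power(self):
        segs = [make_segment(0.95, 0.93, 0.84), make_segment(0.9, 0.89, 0.8)]
        out = compare_tracks(segs)
        assert out["tests"]["S_tad_vs_real"]["low_power"]

    def test_fewer_than_two_undefined(self, caplog):
        with caplog.at_level("WARNING", logger="divecorrect"):
            out = compare_tracks([make_segment(0.9, 0.9, 0.9)])
        assert out["tests"] is None


class TestPerTrackReport:
    def _row(self, ident="a"):
        return {
            "id": ident, "distance_km": 1000.0, "constant_heading_km": 900.0,
            "nbkps": 2, "nbkps_shallow": 1, "S_tad": 0.95, "S_surface": 0.93,
            "S_real": 0.84, "rmse_tad": 18.0, "rmse_surface": 22.0, "rmse_real": 33.0,
        }

    def test_single_track_mean_equals_row(self):
        rep = per_track_report([self._row()])
        mean = rep[rep["id"] == "MEAN"].iloc[0]
        assert mean["S_tad"] == 0.95
        assert mean["distance_km"] == 1000.0

    def test_sum_row_and_share(self):
        rep = per_track_report([self._row("a"), self._row("b")])
        total = rep[rep["id"] == "SUM"].iloc[0]
        assert total["distance_km"] == 2000.0
        assert constant_heading_share(rep) == pytest.approx(90.0)
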