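"""Generator behaviour: determinism, scenario structure and the
consistency of recorded ground truth."""

import numpy as np
import pandas as pd
import pytest

from divecorrect.geodesy import geodesic_inverse
from divecorrect.synthetic import (
    OceanSpec,
    ShearSpec,
    TurtleSpec,
    degrade_observations,
    make_ocean,
    simulate_turtle,
)
from divecorrect.tad import bin_index
from divecorrect.types import PSY4_LAYER_BOUNDS

from conftest import mixture


class TestMakeOcean:
    def test_uniform_scenario_constant_across_layers(self, uniform_ocean):
        field, _ = uniform_ocean
        assert np.all(field.u == 0.2)
        assert np.all(field.v == 0.0)

    def test_shear_reverses_at_layer_17(self, sheared_ocean):
        """+0.3 above 40 m; the sign flips at the layer bounded by 40.3 m."""
        field, _ = sheared_ocean
        assert PSY4_LAYER_BOUNDS[17] == pytest.approx(40.3)
        assert np.all(field.u[:, :17] == 0.3)
        assert np.all(field.u[:, 17:] == -0.3)

    def test_deterministic_given_seed(self):
        spec = OceanSpec(lon_min=50, lon_max=52, lat_min=-5, lat_max=-3,
                         grid_step_deg=0.5, n_days=2, noise_std=0.1)
        f1, _ = make_ocean(spec, seed=9)
        f2, _ = make_ocean(spec, seed=9)
        np.testing.assert_array_equal(f1.u, f2.u)
        f3, _ = make_ocean(spec, seed=10)
        assert not np.array_equal(f1.u, f3.u)

    def test_degenerate_grid_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            OceanSpec(lon_min=50, lon_max=50.1, lat_min=0, lat_max=10, grid_step_deg=0.5)

    def test_shelf_bathymetry(self):
        from divecorrect.synthetic import ShelfSpec

        _, bathy = make_ocean(
            OceanSpec(lon_min=50, lon_max=54, lat_min=-5, lat_max=-1, grid_step_deg=1.0,
                      n_days=1, shelf=ShelfSpec(lon_min=52, lon_max=54, lat_min=-3, lat_max=-1))
        )
        assert bathy.depth_at(50.0, -5.0) == 4000.0
        assert bathy.depth_at(53.0, -2.0) == 100.0


class TestSimulateTurtle:
    def test_zero_current_pure_swim(self, north_swimmer):
        """Heading 0, 0.5 m/s, no current: ground speed 0.5 northward."""
        _, (track, depths, truth) = north_swimmer
        d, az = geodesic_inverse(truth.lon00[0], truth.lat00[0], truth.lon24[0], truth.lat24[0])
        assert d / 86400.0 == pytest.approx(0.5, rel=2e-3)
        assert az == pytest.approx(0.0, abs=0.2) or az == pytest.approx(360.0, abs=0.2)
        assert np.all(truth.current_u == 0.0)

    def test_pure_drift(self, drifter):
        """Swim 0 in a 0.2 m/s eastward ocean: track drifts east at 0.2."""
        _, (track, depths, truth) = drifter
        d, az = geodesic_inverse(truth.lon00[0], truth.lat00[0], truth.lon24[0], truth.lat24[0])
        assert d / 86400.0 == pytest.approx(0.2, rel=2e-3)
        assert az == pytest.approx(90.0, abs=0.5)

    def test_sheared_5050_mean_current_cancels(self, sheared_swimmer):
        """50/50 occupancy across opposing +/-0.3 flows: the time-weighted
        daily mean current is the brute-force average over the records."""
        _, (track, depths, truth) = sheared_swimmer
        # brute-force oracle: +/-0.3 by record depth, averaged per day
        rec = depths.records.copy()
        bins, _ = bin_index(rec["depth"].to_numpy())
        rec["u"] = np.where(PSY4_LAYER_BOUNDS[bins] <= 40.0, 0.3, -0.3)
        rec["day"] = pd.to_datetime(rec["time"]).dt.date
        daily = rec.groupby("day")["u"].mean()
        np.testing.assert_allclose(truth.current_u, daily.to_numpy(), atol=1e-12)
        assert abs(truth.current_u.mean()) < 0.02

    def test_track_exits_grid_names_day(self):
        ocean, _ = make_ocean(
            OceanSpec(lon_min=54, lon_max=56, lat_min=-21, lat_max=-20, grid_step_deg=0.5, n_days=8)
        )
        spec = TurtleSpec(start_lon=55.0, start_lat=-20.3, legs=[(0.0, 5)], swim_speed=0.5,
                          tad_weights=mixture(0.5), seed=1)
        with pytest.raises(ValueError, match=r"left the ocean grid on day \d"):
            simulate_turtle(spec, ocean)

    def test_seeded_run_reproducible(self, still_ocean):
        ocean, _ = still_ocean
        spec = TurtleSpec(start_lon=55.0, start_lat=-20.0, legs=[(45.0, 3)],
                          heading_noise_sd_deg=10.0, tad_weights=mixture(0.5), seed=7)
        t1, d1, tr1 = simulate_turtle(spec, ocean)
        t2, d2, tr2 = simulate_turtle(spec, ocean)
        pd.testing.assert_frame_equal(t1.fixes, t2.fixes)
        pd.testing.assert_frame_equal(d1.records, d2.records)
        np.testing.assert_array_equal(tr1.heading_deg, tr2.heading_deg)


class TestDegradeObservations:
    def test_identity_when_no_degradation(self, north_swimmer):
        spec, (track, depths, _) = north_swimmer
        t2, d2 = degrade_observations(track, depths, spec)
        pd.testing.assert_frame_equal(t2.fixes, track.fixes)
        pd.testing.assert_frame_equal(d2.records, depths.records)

    def test_binomial_thinning_expectation(self, north_swimmer):
        """f = 0.84 on 288 records/day keeps about 46 per day."""
        spec, (track, depths, _) = north_swimmer
        import dataclasses

        spec84 = dataclasses.replace(spec, depth_missing_fraction=0.84)
        _, d2 = degrade_observations(track, depths, spec84, seed=21)
        n_days = spec.n_days
        per_day = len(d2.records) / n_days
        # binomial sd of the 10-day mean is ~2 records/day
        assert per_day == pytest.approx(288 * 0.16, abs=6)

    def test_bad_fraction_rejected(self, north_swimmer):
        spec, (track, depths, _) = north_swimmer
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(spec, depth_missing_fraction=1.5)

    def test_thinning_deterministic(self, north_swimmer):
        spec, (track, depths, _) = north_swimmer
        import dataclasses

        spec50 = dataclasses.replace(spec, depth_missing_fraction=0.5, position_noise_km=2.0)
        t1, d1 = degrade_observations(track, depths, spec50, seed=8)
        t2, d2 = degrade_observations(track, depths, spec50, seed=8)
        pd.testing.assert_frame_equal(d1.records, d2.records)
        pd.testing.assert_frame_equal(t1.fixes, t2.fixes)

    def test_block_gap_removes_days(self, north_swimmer):
        spec, (track, depths, _) = north_swimmer
        import dataclasses

        specg = dataclasses.replace(spec, depth_block_gap_days=[(2, 3)])
        _, d2 = degrade_observations(track, depths, specg)
        days = pd.to_datetime(d2.records["time"]).dt.normalize().unique()
        t0 = track.fixes["time"].iloc[0].normalize()
        missing = {2, 3, 4}
        kept = {int((pd.Timestamp(d) - t0).days) for d in days}
        assert kept.isdisjoint(missing)
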