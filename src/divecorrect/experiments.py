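"""Reference synthetic experiments exercising the full pipeline.

These are the package's own study designs: a breakpoint/heading/speed
recovery study on two-leg migrants in a vertically sheared ocean, a
shear-discrimination study contrasting the relative error inside and
outside a sheared latitude band, and a track-straightening study in an
eddying, partially sheared ocean.  They are used both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .metrics import latitudinal_error_profile, straightness
from .model import CurrentCorrection
from .segmentation import wrap_angle
from .synthetic import EddySpec, OceanSpec, ShearSpec, TurtleSpec, make_ocean, simulate_turtle
from .types import N_LAYERS


def _mixture(above: float, bin_above: int = 9, bin_below: int = 19) -> np.ndarray:
    """Dive mixture putting ``above`` of the day above the 40 m reversal
    (bin 9: 9.6-11.4 m) and the rest below it (bin 19: 47.4-55.8 m)."""
    w = np.zeros(N_LAYERS)
    w[bin_above] = above
    w[bin_below] = 1.0 - above
    return w


def recovery_experiment(
    n_reps: int = 20,
    seed: int = 1,
    leg_days: int = 32,
    heading_noise_sd: float = 8.0,
    swim_speed: float = 0.5,
) -> dict:
    """Breakpoint, heading and swim-speed recovery for two-leg migrants.

    Each replicate simulates a turtle holding one compass heading for
    ``leg_days`` days, then turning by at least 20 degrees for another
    ``leg_days`` days, diving half above / half below the reversal depth
    of a +/-0.3 m/s vertically sheared ocean.  The full pipeline is run
    and the recovered number of breakpoints, breakpoint timing, segment
    headings and TAD-corrected swimming speed are scored against truth.
    """
    master = np.random.default_rng(seed)
    n_days = 2 * leg_days
    ocean_spec = OceanSpec(
        lon_min=25.0, lon_max=85.0, lat_min=-30.0, lat_max=30.0,
        grid_step_deg=2.0, n_days=n_days + 2,
        shear=ShearSpec(u_above=0.3, u_below=-0.3, reversal_depth_m=40.0),
    )
    ocean, _ = make_ocean(ocean_spec, seed=seed)

    successes = 0
    heading_errors = []
    bkp_errors = []
    speed_means = []
    for rep in range(n_reps):
        rep_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        h1 = float(rng.uniform(0.0, 360.0))
        dtheta = float(rng.uniform(20.0, 60.0)) * (1 if rng.random() < 0.5 else -1)
        h2 = (h1 + dtheta) % 360.0
        spec = TurtleSpec(
            start_lon=55.0, start_lat=0.0,
            start_time="2021-01-01T00:00:00",
            legs=[(h1, leg_days), (h2, leg_days)],
            swim_speed=swim_speed,
            tad_weights=_mixture(0.5),
            heading_noise_sd_deg=heading_noise_sd,
            animal_id=f"rep{rep}",
            seed=rep_seed,
        )
        track, depths, truth = simulate_turtle(spec, ocean)
        res = CurrentCorrection(track, depths, ocean).fit()
        seg = res.segmentation

        speed = np.hypot(
            res.kinematics["ustad"].to_numpy(dtype=float),
            res.kinematics["vstad"].to_numpy(dtype=float),
        )
        speed_means.append(float(np.nanmean(speed)))

        ok = seg is not None and seg.n_bkps == 1
        if ok:
            # the retained series may have been trimmed; map to sim days
            first_date = res.filled["tad"]["date"].iat[0]
            day0 = (first_date - truth.dates[0]).days
            bkp_day = seg.breakpoints[0] + day0
            err = abs(bkp_day - truth.breakpoint_days[0])
            bkp_errors.append(err)
            ok = err <= 3
            for s, target in zip(seg.segments, (h1, h2)):
                heading_errors.append(abs(float(wrap_angle(s.theta_bar - target))))
        if ok:
            successes += 1

    speed_means = np.asarray(speed_means)
    return {
        "n_reps": n_reps,
        "success_rate_pct": 100.0 * successes / n_reps,
        "max_heading_error_deg": float(np.max(heading_errors)) if heading_errors else float("nan"),
        "mean_heading_error_deg": float(np.mean(heading_errors)) if heading_errors else float("nan"),
        "mean_bkp_timing_error_days": float(np.mean(bkp_errors)) if bkp_errors else float("nan"),
        "mean_swim_speed": float(speed_means.mean()),
        "max_speed_error": float(np.max(np.abs(speed_means - swim_speed))),
        "true_swim_speed": swim_speed,
    }


def shear_experiment(seed: int = 1, n_days: int = 40) -> dict:
    """Relative error of the surface-only swimming velocity inside and
    outside a vertically sheared latitude band.

    A northward migrant diving half above / half below the reversal
    crosses from a vertically uniform region into a band where the flow
    reverses at depth (+0.3 m/s above 40 m, -0.3 m/s beneath).  In the
    band the surface approximation misstates the encountered current by
    0.3 m/s, so eps should sit far above the 10% benchmark; outside it
    both estimates agree and eps stays below 1%.
    """
    band = (-5.0, 5.0)
    ocean_spec = OceanSpec(
        lon_min=50.0, lon_max=60.0, lat_min=-20.0, lat_max=10.0,
        grid_step_deg=1.0, n_days=n_days + 2,
        shear=ShearSpec(u_above=0.3, u_below=-0.3, reversal_depth_m=40.0,
                        lat_min=band[0], lat_max=band[1]),
    )
    ocean, _ = make_ocean(ocean_spec, seed=seed)
    spec = TurtleSpec(
        start_lon=55.0, start_lat=-15.0,
        legs=[(0.0, n_days)],
        swim_speed=0.5,
        tad_weights=_mixture(0.5),
        animal_id="shear",
        seed=seed,
    )
    track, depths, _ = simulate_turtle(spec, ocean)
    res = CurrentCorrection(track, depths, ocean).fit()
    kin = res.kinematics
    lat = kin["lat12"].to_numpy(dtype=float)
    eps = kin["eps"].to_numpy(dtype=float)
    margin = 1.5  # one grid cell plus a day's travel, to avoid edge cells
    in_band = (lat > band[0] + margin) & (lat < band[1] - margin)
    outside = lat < band[0] - margin
    ok = np.isfinite(eps)
    profile = latitudinal_error_profile(kin)
    return {
        "eps_sheared_min": float(np.min(eps[in_band & ok])),
        "eps_sheared_mean": float(np.mean(eps[in_band & ok])),
        "eps_uniform_max": float(np.max(eps[outside & ok])),
        "eps_uniform_mean": float(np.mean(eps[outside & ok])),
        "n_sheared_days": int((in_band & ok).sum()),
        "n_uniform_days": int((outside & ok).sum()),
        "profile": profile,
    }


def straightening_experiment(seed: int = 1, n_days: int = 50) -> dict:
    """Straightness ordering S(X_tad) >= S(X_0) >= S(X_g) for a straight
    swimmer crossing an eddy field and a sheared band.

    The eddy (present at all layers) bends the real track; crossing the
    sheared band while diving 70% above / 30% below the reversal makes
    the surface correction overshoot by 0.18 m/s there.  The
    TAD-corrected track should recover the straight compass course.
    """
    band = (-5.0, 5.0)
    ocean_spec = OceanSpec(
        lon_min=48.0, lon_max=62.0, lat_min=-22.0, lat_max=10.0,
        grid_step_deg=0.5, n_days=n_days + 2,
        shear=ShearSpec(u_above=0.3, u_below=-0.3, reversal_depth_m=40.0,
                        lat_min=band[0], lat_max=band[1]),
        eddies=[EddySpec(lon=55.5, lat=-11.0, radius_km=150.0, peak_speed=0.3)],
    )
    ocean, _ = make_ocean(ocean_spec, seed=seed)
    spec = TurtleSpec(
        start_lon=55.0, start_lat=-16.0,
        legs=[(0.0, n_days)],
        swim_speed=0.5,
        tad_weights=_mixture(0.7),
        animal_id="straight",
        seed=seed,
    )
    track, depths, _ = simulate_turtle(spec, ocean)
    res = CurrentCorrection(track, depths, ocean).fit()
    t = res.triplet
    out = {}
    for name in ("tad", "surface", "real"):
        lons, lats = t.variant(name)
        out[f"S_{name}"] = straightness(lons, lats)
    return out


def table_arithmetic() -> dict:
    """Cohort arithmetic from the published deployment and segmentation
    tables: mean tag lifetimes (overall and per tag model), the share of
    northward migrants, and the share of open-ocean distance travelled
    under a constant heading."""
    from .datasets import open_ocean_segments, reunion_deployments
    from .io import tag_summary

    meta = reunion_deployments()
    summary = tag_summary(meta)
    seg = open_ocean_segments()
    return {
        "n_tracks": summary["overall"]["n"],
        "mean_lifetime_days": summary["overall"]["mean_days"],
        "mean_lifetime_wc_days": summary["by_tag_model"]["WC"]["mean_days"],
        "mean_lifetime_lotek_days": summary["by_tag_model"]["LOTEK"]["mean_days"],
        "group_north_share_pct": summary["group_shares_pct"]["North"],
        "constant_heading_share_pct": 100.0
        * seg["constant_heading_km"].sum()
        / seg["distance_km"].sum(),
        "total_distance_km": int(seg["distance_km"].sum()),
        "total_nbkps": int(seg["nbkps"].sum()),
        "nbkps_shallow": int(seg["nbkps_shallow"].sum()),
    }
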