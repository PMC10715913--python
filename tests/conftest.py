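"""Shared synthetic fixtures: small oceans and short simulated turtles."""

import numpy as np
import pandas as pd
import pytest

from divecorrect.synthetic import (
    OceanSpec,
    ShearSpec,
    TurtleSpec,
    make_ocean,
    simulate_turtle,
)
from divecorrect.types import N_LAYERS


def mixture(above: float, bin_above: int = 9, bin_below: int = 19) -> np.ndarray:
    w = np.zeros(N_LAYERS)
    w[bin_above] = above
    w[bin_below] = 1.0 - above
    return w


@pytest.fixture(scope="session")
def still_ocean():
    """Motionless ocean, 16 days."""
    return make_ocean(
        OceanSpec(lon_min=50, lon_max=60, lat_min=-25, lat_max=-5, grid_step_deg=0.5, n_days=16)
    )


@pytest.fixture(scope="session")
def uniform_ocean():
    """0.2 m/s eastward everywhere, all layers."""
    return make_ocean(
        OceanSpec(
            lon_min=50, lon_max=60, lat_min=-25, lat_max=-5,
            grid_step_deg=0.5, n_days=16, uniform_u=0.2,
        )
    )


@pytest.fixture(scope="session")
def sheared_ocean():
    """+0.3 m/s above the 40 m reversal, -0.3 m/s beneath."""
    return make_ocean(
        OceanSpec(
            lon_min=50, lon_max=60, lat_min=-25, lat_max=-5,
            grid_step_deg=0.5, n_days=16,
            shear=ShearSpec(u_above=0.3, u_below=-0.3, reversal_depth_m=40.0),
        )
    )


@pytest.fixture(scope="session")
def north_swimmer(still_ocean):
    """10-day northward swimmer at 0.5 m/s in a motionless ocean."""
    ocean, _ = still_ocean
    spec = TurtleSpec(
        start_lon=55.0, start_lat=-20.0, legs=[(0.0, 10)], swim_speed=0.5,
        tad_weights=mixture(0.5), animal_id="north", seed=3,
    )
    return spec, simulate_turtle(spec, ocean)


@pytest.fixture(scope="session")
def drifter(uniform_ocean):
    """Passive 10-day drifter in the 0.2 m/s eastward ocean."""
    ocean, _ = uniform_ocean
    spec = TurtleSpec(
        start_lon=54.0, start_lat=-15.0, legs=[(0.0, 10)], swim_speed=0.0,
        tad_weights=mixture(0.5), animal_id="drift", seed=4,
    )
    return spec, simulate_turtle(spec, ocean)


@pytest.fixture(scope="session")
def sheared_swimmer(sheared_ocean):
    """10-day northward swimmer diving 50/50 across the reversal depth."""
    ocean, _ = sheared_ocean
    spec = TurtleSpec(
        start_lon=55.0, start_lat=-20.0, legs=[(0.0, 10)], swim_speed=0.5,
        tad_weights=mixture(0.5), animal_id="shear", seed=5,
    )
    return spec, simulate_turtle(spec, ocean)


def make_kin(
    n_days: int,
    invalid_days=(),
    vs=(0.3, 0.1),
    vc=(0.1, 0.0),
    start=("2021-01-01", 55.0, -15.0),
) -> pd.DataFrame:
    """Hand-built daily kinematics frame: day i is a TAD gap when listed
    in ``invalid_days``."""
    date0 = pd.Timestamp(start[0])
    rows = []
    for i in range(n_days):
        bad = i in invalid_days
        rows.append(
            {
                "date": (date0 + pd.Timedelta(days=i)).date(),
                "lon12": start[1] + 0.01 * i,
                "lat12": start[2] + 0.01 * i,
                "ug": vs[0] + vc[0],
                "vg": vs[1] + vc[1],
                "uc0": vc[0], "vc0": vc[1],
                "uctad": np.nan if bad else vc[0],
                "vctad": np.nan if bad else vc[1],
                "us0": vs[0], "vs0": vs[1],
                "ustad": np.nan if bad else vs[0],
                "vstad": np.nan if bad else vs[1],
                "tad_valid": not bad,
                "eps": 0.0,
            }
        )
    return pd.DataFrame(rows)
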