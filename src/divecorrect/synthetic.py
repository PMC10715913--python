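"""Synthetic ocean and turtle generator with known ground truth.

The generator emulates the structure of the study system: a layered
current field over the upper 318 m (optionally with a vertical flow
reversal, the signature of monsoon-driven shear), a bathymetry grid
with an optional shallow shelf, and a migrating turtle that follows a
piecewise-constant compass heading at a steady swimming speed while
diving through the layers.  Every stochastic output is reproducible
from (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geodesy import local_step
from .types import (
    N_LAYERS,
    PSY4_LAYER_BOUNDS,
    RECORDS_PER_DAY,
    BathymetryGrid,
    CurrentField,
    DepthSeries,
    RawTrack,
    heading_to_uv,
)

STEP_SECONDS = 300  # 5-minute simulation step


@dataclass
class ShearSpec:
    """Two-layer flow: (u_above, v_above) for layers whose bound is at or
    above ``reversal_depth_m``, (u_below, v_below) beneath.  If a latitude
    band is given the shear applies only there."""

    u_above: float = 0.3
    v_above: float = 0.0
    u_below: float = -0.3
    v_below: float = 0.0
    reversal_depth_m: float = 40.0
    lat_min: Optional[float] = None
    lat_max: Optional[float] = None


@dataclass
class EddySpec:
    """A stationary axisymmetric eddy applied to every layer: azimuthal
    speed peaks at ``peak_speed`` on the ring r = radius_km."""

    lon: float
    lat: float
    radius_km: float
    peak_speed: float
    sign: int = 1  # +1 counter-clockwise


@dataclass
class ShelfSpec:
    """Rectangular shallow shelf in an otherwise deep ocean."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    depth_m: float = 100.0


@dataclass
class OceanSpec:
    lon_min: float = 50.0
    lon_max: float = 60.0
    lat_min: float = -25.0
    lat_max: float = 5.0
    grid_step_deg: float = 0.5
    n_days: int = 90
    start_date: str = "2021-01-01"
    layer_bounds: np.ndarray = field(default_factory=lambda: PSY4_LAYER_BOUNDS.copy())
    uniform_u: float = 0.0
    uniform_v: float = 0.0
    shear: Optional[ShearSpec] = None
    eddies: list = field(default_factory=list)
    shelf: Optional[ShelfSpec] = None
    deep_depth_m: float = 4000.0
    noise_std: float = 0.0  # iid per-node velocity noise, m/s

    def __post_init__(self):
        lb = np.asarray(self.layer_bounds, dtype=float)
        if np.any(np.diff(lb) <= 0):
            raise ValueError("layer bounds must increase strictly")
        if self.lon_max - self.lon_min < self.grid_step_deg or self.lat_max - self.lat_min < self.grid_step_deg:
            raise ValueError("degenerate ocean grid")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


def make_ocean(spec: OceanSpec, seed: int = 0) -> tuple[CurrentField, BathymetryGrid]:
    """Build the gridded current field and bathymetry for a scenario.

    Deterministic given (spec, seed); the sheared scenario reverses the
    flow across the layer whose bound first exceeds the reversal depth.
    """
    lons = np.arange(spec.lon_min, spec.lon_max + spec.grid_step_deg / 2, spec.grid_step_deg)
    lats = np.arange(spec.lat_min, spec.lat_max + spec.grid_step_deg / 2, spec.grid_step_deg)
    lb = np.asarray(spec.layer_bounds, dtype=float)
    nz, ny, nx = len(lb), len(lats), len(lons)
    times = (
        np.datetime64(spec.start_date, "ns")
        + np.arange(spec.n_days) * np.timedelta64(1, "D")
        + np.timedelta64(12, "h")
    )
    nt = spec.n_days

    u = np.full((nt, nz, ny, nx), spec.uniform_u, dtype=float)
    v = np.full((nt, nz, ny, nx), spec.uniform_v, dtype=float)

    if spec.shear is not None:
        sh = spec.shear
        above = lb <= sh.reversal_depth_m
        in_band = np.ones(ny, dtype=bool)
        if sh.lat_min is not None:
            in_band &= lats >= sh.lat_min
        if sh.lat_max is not None:
            in_band &= lats <= sh.lat_max
        zi = np.where(above)[0]
        zb = np.where(~above)[0]
        for comp, va, vb in ((u, sh.u_above, sh.u_below), (v, sh.v_above, sh.v_below)):
            comp[:, zi[:, None], in_band, :] = va
            comp[:, zb[:, None], in_band, :] = vb

    for eddy in spec.eddies:
        glon, glat = np.meshgrid(lons, lats)
        mlon = 111320.0 * np.cos(np.radians(eddy.lat))
        dx = (glon - eddy.lon) * mlon / 1000.0
        dy = (glat - eddy.lat) * 110574.0 / 1000.0
        r = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            speed = eddy.peak_speed * (r / eddy.radius_km) * np.exp(1.0 - r / eddy.radius_km)
            eu = np.where(r > 0, -dy / r * speed * eddy.sign, 0.0)
            ev = np.where(r > 0, dx / r * speed * eddy.sign, 0.0)
        u += eu[None, None, :, :]
        v += ev[None, None, :, :]

    if spec.noise_std > 0:
        rng = np.random.default_rng(seed)
        u += rng.normal(0.0, spec.noise_std, u.shape)
        v += rng.normal(0.0, spec.noise_std, v.shape)

    depth = np.full((ny, nx), spec.deep_depth_m, dtype=float)
    if spec.shelf is not None:
        s = spec.shelf
        sel = (
            (lats[:, None] >= s.lat_min)
            & (lats[:, None] <= s.lat_max)
            & (lons[None, :] >= s.lon_min)
            & (lons[None, :] <= s.lon_max)
        )
        depth[sel] = s.depth_m

    field_ = CurrentField(times=times, layer_bounds=lb, lats=lats, lons=lons, u=u, v=v)
    return field_, BathymetryGrid(lats=lats, lons=lons, depth_m=depth)


# ---------------------------------------------------------------- turtle


@dataclass
class TurtleSpec:
    start_lon: float = 55.0
    start_lat: float = -20.0
    start_time: str = "2021-01-01T00:00:00"
    legs: list = field(default_factory=lambda: [(0.0, 30)])  # (heading deg, days)
    swim_speed: float = 0.5  # m/s; steady migratory cruise speed
    tad_weights: Optional[np.ndarray] = None  # daily dive mixture over the 30 bins
    heading_noise_sd_deg: float = 0.0  # day-to-day compass scatter
    position_noise_km: float = 0.0  # observation noise on fixes
    fix_interval_hours: float = 1.0
    depth_missing_fraction: float = 0.0
    depth_block_gap_days: list = field(default_factory=list)  # (start_day, n_days)
    animal_id: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if self.swim_speed < 0:
            raise ValueError("swim speed must be >= 0")
        for _, dur in self.legs:
            if dur < 1:
                raise ValueError("leg durations must be >= 1 day")
        if not 0.0 <= self.depth_missing_fraction <= 1.0:
            raise ValueError("depth_missing_fraction must lie in [0, 1]")
        if self.tad_weights is None:
            w = np.zeros(N_LAYERS)
            w[9] = 0.5   # (9.6, 11.4] m
            w[19] = 0.5  # (47.4, 55.8] m
            self.tad_weights = w
        w = np.asarray(self.tad_weights, dtype=float)
        if w.shape != (N_LAYERS,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("tad_weights must be 30 non-negative values with positive sum")
        self.tad_weights = w / w.sum()

    @property
    def n_days(self) -> int:
        return int(sum(d for _, d in self.legs))

    @property
    def breakpoint_days(self) -> list[int]:
        cum = np.cumsum([d for _, d in self.legs])[:-1]
        return [int(c) for c in cum]


@dataclass
class TruthRecord:
    """Per-day ground truth recorded by the simulator."""

    dates: list
    heading_deg: np.ndarray
    swim_u: np.ndarray
    swim_v: np.ndarray
    current_u: np.ndarray  # daily mean encountered current
    current_v: np.ndarray
    lon00: np.ndarray
    lat00: np.ndarray
    lon12: np.ndarray
    lat12: np.ndarray
    lon24: np.ndarray
    lat24: np.ndarray
    breakpoint_days: list
    swim_speed: float

    def to_json(self, path) -> None:
        data = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        data["dates"] = [str(d) for d in self.dates]
        import pathlib

        pathlib.Path(path).write_text(json.dumps(data, indent=2))


def _bin_representative_depths(bounds: np.ndarray) -> np.ndarray:
    """One representative depth per bin: 0 for the surface bin, the
    interval midpoint elsewhere."""
    mids = np.empty(len(bounds))
    mids[0] = 0.0
    mids[1:] = 0.5 * (bounds[:-1] + bounds[1:])
    return mids


class _FieldSampler:
    """Fast nearest-node sampler used inside the simulation loop."""

    def __init__(self, field_: CurrentField):
        self.f = field_
        self.lat0 = float(field_.lats[0])
        self.lon0 = float(field_.lons[0])
        self.dlat = float(field_.lats[1] - field_.lats[0])
        self.dlon = float(field_.lons[1] - field_.lons[0])
        self.ny = len(field_.lats)
        self.nx = len(field_.lons)

    def sample(self, t: int, layer: int, lon: float, lat: float) -> tuple[float, float]:
        i = int(round((lat - self.lat0) / self.dlat))
        j = int(round((lon - self.lon0) / self.dlon))
        if not (0 <= i < self.ny and 0 <= j < self.nx):
            raise ValueError("position outside current grid")
        return float(self.f.u[t, layer, i, j]), float(self.f.v[t, layer, i, j])


def simulate_turtle(
    spec: TurtleSpec, ocean: CurrentField
) -> tuple[RawTrack, DepthSeries, TruthRecord]:
    """Forward-simulate a diving migrant through the gridded currents.

    Every 5-minute step the turtle occupies a depth bin drawn from its
    dive mixture and is advected by (swim vector + current at that depth)
    for 300 s.  The observed ground velocity therefore decomposes exactly
    into the steady swim vector plus the time-at-depth-averaged current.
    """
    rng = np.random.default_rng(spec.seed)
    bounds = ocean.layer_bounds
    rep_depth = _bin_representative_depths(bounds)
    sampler = _FieldSampler(ocean)

    t0 = pd.Timestamp(spec.start_time)
    n_days = spec.n_days
    day_headings = []
    for heading, dur in spec.legs:
        day_headings.extend([heading] * int(dur))
    day_headings = np.asarray(day_headings, dtype=float)
    if spec.heading_noise_sd_deg > 0:
        day_headings = day_headings + rng.normal(0.0, spec.heading_noise_sd_deg, n_days)

    lon, lat = spec.start_lon, spec.start_lat
    fix_every = max(1, int(round(spec.fix_interval_hours * 3600 / STEP_SECONDS)))

    fixes_t, fixes_lon, fixes_lat = [], [], []
    rec_t, rec_d = [], []
    tr = {
        k: np.zeros(n_days)
        for k in (
            "heading", "su", "sv", "cu", "cv",
            "lon00", "lat00", "lon12", "lat12", "lon24", "lat24",
        )
    }
    dates = []

    step = 0
    for d in range(n_days):
        day_start = t0 + pd.Timedelta(days=d)
        dates.append(day_start.date())
        tday = ocean.time_index(day_start)
        swim = heading_to_uv(day_headings[d], spec.swim_speed)
        layers = rng.choice(N_LAYERS, size=RECORDS_PER_DAY, p=spec.tad_weights)
        tr["heading"][d] = day_headings[d] % 360.0
        tr["su"][d], tr["sv"][d] = swim.u, swim.v
        tr["lon00"][d], tr["lat00"][d] = lon, lat
        cu = cv = 0.0
        for k in range(RECORDS_PER_DAY):
            if step % fix_every == 0:
                fixes_t.append(t0 + pd.Timedelta(seconds=step * STEP_SECONDS))
                fixes_lon.append(lon)
                fixes_lat.append(lat)
            rec_t.append(t0 + pd.Timedelta(seconds=step * STEP_SECONDS))
            rec_d.append(rep_depth[layers[k]])
            try:
                uc, vc = sampler.sample(tday, int(layers[k]), lon, lat)
            except ValueError as err:
                raise ValueError(f"track left the ocean grid on day {d}") from err
            cu += uc
            cv += vc
            lon, lat = local_step(
                lon, lat, (swim.u + uc) * STEP_SECONDS, (swim.v + vc) * STEP_SECONDS
            )
            step += 1
            if k == RECORDS_PER_DAY // 2 - 1:
                tr["lon12"][d], tr["lat12"][d] = lon, lat
        tr["cu"][d] = cu / RECORDS_PER_DAY
        tr["cv"][d] = cv / RECORDS_PER_DAY
        tr["lon24"][d], tr["lat24"][d] = lon, lat

    # final fix at the end of the last day so interpolation is supported
    fixes_t.append(t0 + pd.Timedelta(seconds=step * STEP_SECONDS))
    fixes_lon.append(lon)
    fixes_lat.append(lat)

    track = RawTrack(
        animal_id=spec.animal_id,
        fixes=pd.DataFrame({"time": fixes_t, "lon": fixes_lon, "lat": fixes_lat}),
    )
    depths = DepthSeries(
        animal_id=spec.animal_id, records=pd.DataFrame({"time": rec_t, "depth": rec_d})
    )
    truth = TruthRecord(
        dates=dates,
        heading_deg=tr["heading"],
        swim_u=tr["su"],
        swim_v=tr["sv"],
        current_u=tr["cu"],
        current_v=tr["cv"],
        lon00=tr["lon00"],
        lat00=tr["lat00"],
        lon12=tr["lon12"],
        lat12=tr["lat12"],
        lon24=tr["lon24"],
        lat24=tr["lat24"],
        breakpoint_days=spec.breakpoint_days,
        swim_speed=spec.swim_speed,
    )
    return track, depths, truth


def degrade_observations(
    track: RawTrack, depths: DepthSeries, spec: TurtleSpec, seed: Optional[int] = None
) -> tuple[RawTrack, DepthSeries]:
    """Apply the observation model: zero-mean position noise on fixes,
    independent thinning of depth records (retained fraction 1 - f) and
    optional whole-day block gaps in the depth stream."""
    f = spec.depth_missing_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError("missingness fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    fixes = track.fixes.copy()
    if spec.position_noise_km > 0:
        sd_m = spec.position_noise_km * 1000.0
        dx = rng.normal(0.0, sd_m, len(fixes))
        dy = rng.normal(0.0, sd_m, len(fixes))
        pts = [
            local_step(lo, la, x, y)
            for lo, la, x, y in zip(fixes["lon"], fixes["lat"], dx, dy)
        ]
        fixes["lon"] = [p[0] for p in pts]
        fixes["lat"] = [p[1] for p in pts]

    records = depths.records.copy()
    if f > 0:
        keep = rng.random(len(records)) >= f
        records = records[keep]
    if spec.depth_block_gap_days:
        t0 = track.fixes["time"].iloc[0].normalize()
        day = ((records["time"] - t0) / pd.Timedelta(days=1)).astype(int)
        drop = np.zeros(len(records), dtype=bool)
        for start, n in spec.depth_block_gap_days:
            drop |= ((day >= start) & (day < start + n)).to_numpy()
        records = records[~drop]

    return (
        RawTrack(animal_id=track.animal_id, fixes=fixes.reset_index(drop=True)),
        DepthSeries(animal_id=depths.animal_id, records=records.reset_index(drop=True)),
    )
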