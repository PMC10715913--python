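"""Domain containers shared by the pipeline stages.

Tabular data (fixes, depth records, daily kinematics) live in pandas
DataFrames; gridded fields are thin dataclasses over numpy arrays with
xarray used only at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Lower 30 vertical layers of a 1/12-degree operational ocean model
#: (metres).  These depths delimit the time-at-depth bins: bin 0 holds the
#: surface (0 m exactly) and bin n holds depths in (bounds[n-1], bounds[n]].
PSY4_LAYER_BOUNDS: np.ndarray = np.array(
    [
        0.0, 0.5, 1.5, 2.6, 3.8, 5.1, 6.4, 7.9, 9.6, 11.4,
        13.5, 15.8, 18.5, 21.6, 25.2, 29.4, 34.4, 40.3, 47.4, 55.8,
        65.8, 77.8, 92.3, 109.7, 130.7, 155.8, 186.1, 222.5, 266.0, 318.1,
    ]
)

N_LAYERS = len(PSY4_LAYER_BOUNDS)

#: Nominal number of 5-minute depth records in a full day.
RECORDS_PER_DAY = 288


def _check_lon(lon) -> None:
    lon = np.asarray(lon, dtype=float)
    if np.any((lon < -180.0) | (lon >= 180.0)):
        raise ValueError("lon out of range [-180, 180)")


def _check_lat(lat) -> None:
    lat = np.asarray(lat, dtype=float)
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValueError("lat out of range [-90, 90]")


@dataclass(frozen=True)
class GeoPosition:
    """A longitude/latitude pair with an optional UTC instant."""

    lon: float
    lat: float
    time: Optional[pd.Timestamp] = None

    def __post_init__(self):
        _check_lon(self.lon)
        _check_lat(self.lat)
        if self.time is not None and self.time.tzinfo is not None:
            object.__setattr__(self, "time", self.time.tz_convert("UTC").tz_localize(None))


@dataclass(frozen=True)
class VelocityVector:
    """Horizontal velocity with eastward (u) and northward (v) components
    in m s^-1.  Heading is measured clockwise from north."""

    u: float
    v: float

    @property
    def speed(self) -> float:
        return math.hypot(self.u, self.v)

    @property
    def heading(self) -> float:
        """Degrees clockwise from north in [0, 360); nan at zero speed."""
        if self.speed == 0.0:
            return float("nan")
        return math.degrees(math.atan2(self.u, self.v)) % 360.0

    def __add__(self, other: "VelocityVector") -> "VelocityVector":
        return VelocityVector(self.u + other.u, self.v + other.v)

    def __sub__(self, other: "VelocityVector") -> "VelocityVector":
        return VelocityVector(self.u - other.u, self.v - other.v)


def heading_to_uv(heading_deg: float, speed: float) -> VelocityVector:
    th = math.radians(heading_deg)
    return VelocityVector(speed * math.sin(th), speed * math.cos(th))


@dataclass
class RawTrack:
    """Time-ordered satellite fixes for one animal.

    ``fixes`` has columns ``time`` (tz-naive UTC), ``lon``, ``lat`` and
    optionally ``quality``; rows are strictly increasing in time.
    """

    animal_id: str
    fixes: pd.DataFrame
    tag_model: Optional[str] = None
    group: Optional[str] = None
    scl_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    duration_days: Optional[float] = None

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError(f"track {self.animal_id}: fewer than 2 fixes")
        t = self.fixes["time"].to_numpy()
        if not np.all(t[1:] > t[:-1]):
            raise ValueError(f"track {self.animal_id}: times not strictly increasing")
        _check_lon(self.fixes["lon"].to_numpy())
        _check_lat(self.fixes["lat"].to_numpy())

    @property
    def span_days(self) -> float:
        t = self.fixes["time"]
        return (t.iloc[-1] - t.iloc[0]) / pd.Timedelta(days=1)


@dataclass
class DepthSeries:
    """5-minute depth records for one animal: columns ``time``, ``depth``
    (metres, positive down)."""

    animal_id: str
    records: pd.DataFrame

    def __post_init__(self):
        t = self.records["time"].to_numpy()
        if len(t) and not np.all(t[1:] > t[:-1]):
            raise ValueError(f"depth series {self.animal_id}: times not strictly increasing")
        d = self.records["depth"].to_numpy(dtype=float)
        if np.any(d[np.isfinite(d)] < 0):
            raise ValueError(f"depth series {self.animal_id}: negative depth")


@dataclass
class CurrentField:
    """Daily-mean gridded horizontal currents on model layers.

    ``u``/``v`` have shape (time, layer, lat, lon) in m s^-1; land or
    otherwise missing nodes are NaN.  Each daily field is centred at
    12:00 UTC and is used for the whole calendar day.
    """

    times: np.ndarray            # datetime64[ns], daily, centred 12:00 UTC
    layer_bounds: np.ndarray     # (nz,) metres, strictly increasing, first 0
    lats: np.ndarray             # (ny,) degrees north, uniform
    lons: np.ndarray             # (nx,) degrees east, uniform
    u: np.ndarray                # (nt, nz, ny, nx)
    v: np.ndarray

    def __post_init__(self):
        lb = np.asarray(self.layer_bounds, dtype=float)
        if lb[0] != 0.0 or np.any(np.diff(lb) <= 0):
            raise ValueError("layer bounds must start at 0 and increase strictly")
        for ax in (self.lats, self.lons):
            ax = np.asarray(ax, dtype=float)
            if len(ax) < 2:
                raise ValueError("degenerate grid axis")
            step = np.diff(ax)
            if np.any(step <= 0) or not np.allclose(step, step[0], rtol=1e-6):
                raise ValueError("grid axes must be uniform and increasing")
        if self.u.shape != (len(self.times), len(lb), len(self.lats), len(self.lons)):
            raise ValueError("u shape inconsistent with axes")
        if self.v.shape != self.u.shape:
            raise ValueError("u/v shape mismatch")

    def time_index(self, when) -> int:
        """Index of the daily field covering the calendar day of ``when``."""
        day = np.datetime64(pd.Timestamp(when).normalize(), "ns")
        days = self.times.astype("datetime64[D]").astype("datetime64[ns]")
        idx = np.nonzero(days == day)[0]
        if len(idx) == 0:
            raise KeyError(f"no current field for day {day}")
        return int(idx[0])

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lons[0] <= lon <= self.lons[-1]
            and self.lats[0] <= lat <= self.lats[-1]
        )


@dataclass
class BathymetryGrid:
    """Seafloor depth in metres, positive down, on a regular lon/lat grid."""

    lats: np.ndarray
    lons: np.ndarray
    depth_m: np.ndarray  # (ny, nx)

    def __post_init__(self):
        if self.depth_m.shape != (len(self.lats), len(self.lons)):
            raise ValueError("depth grid shape inconsistent with axes")

    def depth_at(self, lon: float, lat: float) -> float:
        """Nearest-node seafloor depth; nan off-grid."""
        if not (
            self.lons[0] <= lon <= self.lons[-1] and self.lats[0] <= lat <= self.lats[-1]
        ):
            return float("nan")
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return float(self.depth_m[i, j])


@dataclass
class DailyTrack:
    """A track regularised to the daily frame.

    One row per calendar day with interpolated positions at 00:00,
    12:00 (the daily midpoint x(t_mid)) and 24:00 UTC, and flags saying
    whether each instant was bracketed by real fixes (no extrapolation is
    ever performed).
    """

    animal_id: str
    days: pd.DataFrame  # date, lon00, lat00, lon12, lat12, lon24, lat24, sup00, sup12, sup24

    def __len__(self):
        return len(self.days)

    @property
    def supported(self) -> pd.Series:
        d = self.days
        return d["sup00"] & d["sup12"] & d["sup24"]


@dataclass
class TADHistogram:
    """Normalised daily time-at-depth weights over the model layer bins."""

    day: object                  # datetime.date
    weights: np.ndarray          # (N_LAYERS,)
    n_records: int
    valid: bool
    n_clamped: int = 0

    @property
    def completeness(self) -> float:
        return self.n_records / RECORDS_PER_DAY

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if self.n_records > 0 and abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("TAD weights must sum to 1")
        if np.any(w < 0):
            raise ValueError("TAD weights must be non-negative")


@dataclass
class Segment:
    """A constant-heading leg proposed by the segmentation."""

    start: int                   # day index, inclusive
    end: int                     # day index, exclusive
    theta_bar: float             # circular mean heading, deg in [0, 360)
    rmse: float                  # circular RMSE, deg
    valid: bool
    straightness: dict = field(default_factory=dict)   # variant -> S
    mean_rmse: dict = field(default_factory=dict)      # variant -> heading RMSE about theta_bar
    shallow: Optional[bool] = None
    delta_theta: Optional[float] = None  # to next valid segment, (-180, 180]

    @property
    def n_days(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    """Breakpoints, cost curve and segment statistics for one heading series."""

    n_obs: int
    cost_curve: np.ndarray       # Cost(n) for n = 0..max explored
    breakpoint_path: list        # breakpoint_path[n] = sorted breakpoints for n splits
    n_bkps: int                  # chosen by the elbow rule
    elbow_warning: bool = False
    segments: list = field(default_factory=list)

    @property
    def breakpoints(self) -> list:
        return self.breakpoint_path[self.n_bkps]


@dataclass
class CorrectedTrack:
    """Fictive track from integrating swimming velocity: the animal's
    movement in a motionless ocean."""

    animal_id: str
    variant: str                 # "tad" | "surface"
    days: pd.DataFrame           # date, lon, lat, filled

    def positions(self):
        return self.days["lon"].to_numpy(), self.days["lat"].to_numpy()


@dataclass
class TrackTriplet:
    """Aligned real, surface-corrected and TAD-corrected daily positions."""

    dates: np.ndarray
    real: tuple[np.ndarray, np.ndarray]
    surface: tuple[np.ndarray, np.ndarray]
    tad: tuple[np.ndarray, np.ndarray]

    def variant(self, name: str):
        return {"real": self.real, "surface": self.surface, "tad": self.tad}[name]
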