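"""Regularisation of raw fixes to the daily frame, ground velocity, and
open-ocean masking.

Positions are interpolated at 00:00 and 12:00 UTC by time-linear
great-circle interpolation between the bracketing fixes; no
extrapolation is performed beyond the first and last fix.  The daily
ground velocity at x(t_mid) is the geodesic displacement between the
bracketing midnights divided by 86 400 s.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geodesy import geodesic_inverse, great_circle_interpolate, local_displacement
from .types import BathymetryGrid, DailyTrack, RawTrack

log = logging.getLogger("divecorrect")

SECONDS_PER_DAY = 86400.0


def _interp_at(times: np.ndarray, lons, lats, target: pd.Timestamp):
    """Great-circle interpolation at one instant; (nan, nan, False) when
    the instant is not bracketed by fixes."""
    t = np.datetime64(target, "ns")
    if t < times[0] or t > times[-1]:
        return np.nan, np.nan, False
    j = int(np.searchsorted(times, t, side="left"))
    if times[j] == t:
        return float(lons[j]), float(lats[j]), True
    i = j - 1
    frac = float((t - times[i]) / (times[j] - times[i]))
    lon, lat = great_circle_interpolate(lons[i], lats[i], lons[j], lats[j], frac)
    return lon, lat, True


def interpolate_daily(track: RawTrack) -> DailyTrack:
    """Interpolate the track at 00:00, 12:00 and 24:00 UTC of every
    calendar day touched by the fixes."""
    fixes = track.fixes
    times = fixes["time"].to_numpy()
    lons = fixes["lon"].to_numpy(dtype=float)
    lats = fixes["lat"].to_numpy(dtype=float)

    first_day = pd.Timestamp(times[0]).normalize()
    last_day = pd.Timestamp(times[-1]).normalize()
    days = pd.date_range(first_day, last_day, freq="D")
    rows = []
    for day in days:
        p00 = _interp_at(times, lons, lats, day)
        p12 = _interp_at(times, lons, lats, day + pd.Timedelta(hours=12))
        p24 = _interp_at(times, lons, lats, day + pd.Timedelta(hours=24))
        rows.append(
            {
                "date": day.date(),
                "lon00": p00[0], "lat00": p00[1], "sup00": p00[2],
                "lon12": p12[0], "lat12": p12[1], "sup12": p12[2],
                "lon24": p24[0], "lat24": p24[1], "sup24": p24[2],
            }
        )
    return DailyTrack(animal_id=track.animal_id, days=pd.DataFrame(rows))


def ground_velocity(daily: DailyTrack) -> pd.DataFrame:
    """Per-day eastward/northward ground velocity (m/s) at x(t_mid).

    Magnitude is the geodesic distance between the positions 12 h before
    and after the midpoint; the direction comes from the local-metric
    displacement at the mean latitude.  Days without both bracketing
    positions are NaN.
    """
    d = daily.days
    n = len(d)
    ug = np.full(n, np.nan)
    vg = np.full(n, np.nan)
    for i in range(n):
        if not (d["sup00"].iat[i] and d["sup24"].iat[i]):
            continue
        lon1, lat1 = d["lon00"].iat[i], d["lat00"].iat[i]
        lon2, lat2 = d["lon24"].iat[i], d["lat24"].iat[i]
        dist, _ = geodesic_inverse(lon1, lat1, lon2, lat2)
        if dist == 0.0:
            ug[i] = vg[i] = 0.0
            continue
        dx, dy = local_displacement(lon1, lat1, lon2, lat2)
        norm = np.hypot(dx, dy)
        speed = dist / SECONDS_PER_DAY
        ug[i] = speed * dx / norm
        vg[i] = speed * dy / norm
    out = d[["date"]].copy()
    out["ug"] = ug
    out["vg"] = vg
    return out


def mask_open_ocean(
    daily: DailyTrack,
    bathy: BathymetryGrid,
    coastal_polygon=None,
    config: AnalysisConfig | None = None,
) -> DailyTrack:
    """Truncate the daily track at the end of its open-ocean transect.

    If a coastal polygon is supplied the track is cut at the first day
    whose midpoint falls inside it; otherwise at the first run of
    ``coastal_consec_days`` consecutive days over water shallower than
    ``shallow_bathy_m``.
    """
    config = config or AnalysisConfig()
    d = daily.days
    cut = None
    if coastal_polygon is not None:
        from shapely.geometry import Point

        for i in range(len(d)):
            if not d["sup12"].iat[i]:
                continue
            if coastal_polygon.contains(Point(d["lon12"].iat[i], d["lat12"].iat[i])):
                cut = i
                break
    else:
        run = 0
        for i in range(len(d)):
            if not d["sup12"].iat[i]:
                run = 0
                continue
            depth = bathy.depth_at(d["lon12"].iat[i], d["lat12"].iat[i])
            if np.isfinite(depth) and depth < config.shallow_bathy_m:
                run += 1
                if run >= config.coastal_consec_days:
                    cut = i - run + 1
                    break
            else:
                run = 0
    if cut is None:
        return daily
    if cut == 0:
        log.warning("track %s: entirely coastal, empty open-ocean transect", daily.animal_id)
    return DailyTrack(animal_id=daily.animal_id, days=d.iloc[:cut].reset_index(drop=True))
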