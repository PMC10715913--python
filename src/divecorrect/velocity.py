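"""Swimming-velocity decomposition: Vs = Vg - Vc.

Two variants are carried side by side: Vs0 subtracts the surface
current (the classical upper-layer approximation) and Vs[TAD]
subtracts the time-at-depth-weighted current.  Their disagreement is
summarised by the relative error

    eps = ||Vs[TAD] - Vs0|| / ||Vs[TAD]||,

undefined (not infinite) when the denominator falls below a small
speed floor.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .currents import surface_current, tad_weighted_current
from .preprocess import ground_velocity
from .types import CurrentField, DailyTrack, VelocityVector


def swimming_velocity(vg: VelocityVector | None, vc: VelocityVector | None) -> VelocityVector | None:
    """Componentwise Vg - Vc; missing input propagates to missing output."""
    if vg is None or vc is None:
        return None
    return vg - vc


def relative_error(
    vstad: VelocityVector | None, vs0: VelocityVector | None, floor: float = 0.01
) -> float:
    """Relative disagreement of the surface-only estimate with respect to
    the TAD estimate; nan when undefined."""
    if vstad is None or vs0 is None:
        return float("nan")
    denom = vstad.speed
    if denom <= floor:
        return float("nan")
    return (vstad - vs0).speed / denom


def assemble_kinematics(
    daily: DailyTrack,
    field: CurrentField,
    tads: list,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """One row per day with ground, current and swimming velocities.

    Columns: date, lon12, lat12, ug/vg, uc0/vc0, uctad/vctad, us0/vs0,
    ustad/vstad, tad_valid, eps.  The frame's ``attrs`` carry the share
    of days with a valid Vs[TAD] (``coverage``).
    """
    config = config or AnalysisConfig()
    d = daily.days
    tad_by_day = {t.day: t for t in tads}
    if len(d) and not set(d["date"]) & set(tad_by_day):
        raise ValueError("daily track and TAD histograms share no dates (misaligned inputs?)")
    gv = ground_velocity(daily)

    rows = []
    for i in range(len(d)):
        date = d["date"].iat[i]
        lon12, lat12, sup12 = d["lon12"].iat[i], d["lat12"].iat[i], d["sup12"].iat[i]
        row = {
            "date": date, "lon12": lon12, "lat12": lat12,
            "ug": gv["ug"].iat[i], "vg": gv["vg"].iat[i],
            "uc0": np.nan, "vc0": np.nan, "uctad": np.nan, "vctad": np.nan,
            "us0": np.nan, "vs0": np.nan, "ustad": np.nan, "vstad": np.nan,
            "tad_valid": False, "eps": np.nan,
        }
        tad = tad_by_day.get(date)
        if sup12 and np.isfinite(lon12):
            when = pd.Timestamp(date)
            vc0 = surface_current(field, lon12, lat12, when, config)
            if vc0 is not None:
                row["uc0"], row["vc0"] = vc0.u, vc0.v
            if tad is not None and tad.valid:
                row["tad_valid"] = True
                vctad = tad_weighted_current(field, lon12, lat12, when, tad, config)
                if vctad is not None:
                    row["uctad"], row["vctad"] = vctad.u, vctad.v
            vg = None
            if math.isfinite(row["ug"]):
                vg = VelocityVector(row["ug"], row["vg"])
            vs0 = swimming_velocity(vg, vc0)
            vstad = swimming_velocity(
                vg,
                VelocityVector(row["uctad"], row["vctad"]) if math.isfinite(row["uctad"]) else None,
            )
            if vs0 is not None:
                row["us0"], row["vs0"] = vs0.u, vs0.v
            if vstad is not None:
                row["ustad"], row["vstad"] = vstad.u, vstad.v
            row["eps"] = relative_error(vstad, vs0, config.eps_floor)
        rows.append(row)

    kin = pd.DataFrame(rows)
    valid = kin["ustad"].notna()
    kin.attrs["coverage"] = float(valid.mean()) if len(kin) else float("nan")
    kin.attrs["animal_id"] = daily.animal_id
    return kin
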