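"""Encountered-current evaluation at daily midpoint positions.

Horizontal interpolation is inverse-distance weighting over the four
grid nodes surrounding the query point, with distances measured in
local metres (cos-latitude scaling).  The daily field centred at 12:00
UTC is used for the whole calendar day.  The TAD-weighted current is
the dive-occupancy average of the per-layer interpolated currents:

    Vc[TAD] = sum_n TAD_n * Vc_n
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .types import CurrentField, TADHistogram, VelocityVector

_NODE_EXACT_M = 1.0  # closer than this to a node returns the node value


def idw_horizontal(
    field: CurrentField, lon: float, lat: float, day, layer: int,
    power: float = 2.0,
) -> VelocityVector | None:
    """IDW-interpolated current at one layer; None when every
    surrounding node is land/missing."""
    if not field.contains(lon, lat):
        raise ValueError(f"position ({lon}, {lat}) outside current grid")
    t = day if isinstance(day, (int, np.integer)) else field.time_index(day)

    lats, lons = field.lats, field.lons
    i = int(np.clip(np.searchsorted(lats, lat) - 1, 0, len(lats) - 2))
    j = int(np.clip(np.searchsorted(lons, lon) - 1, 0, len(lons) - 2))

    mlon = 111320.0 * np.cos(np.radians(lat))
    mlat = 110574.0
    us, vs, ws = [], [], []
    for ii in (i, i + 1):
        for jj in (j, j + 1):
            u = field.u[t, layer, ii, jj]
            v = field.v[t, layer, ii, jj]
            d = np.hypot((lon - lons[jj]) * mlon, (lat - lats[ii]) * mlat)
            if d < _NODE_EXACT_M:
                if np.isnan(u):
                    return None
                return VelocityVector(float(u), float(v))
            if np.isnan(u) or np.isnan(v):
                continue
            us.append(u)
            vs.append(v)
            ws.append(d ** -power)
    if not ws:
        return None
    w = np.asarray(ws)
    w = w / w.sum()
    return VelocityVector(float(np.dot(w, us)), float(np.dot(w, vs)))


def surface_current(
    field: CurrentField, lon: float, lat: float, day, config: AnalysisConfig | None = None
) -> VelocityVector | None:
    """Vc0: the surface-layer current at the daily midpoint."""
    power = (config or AnalysisConfig()).idw_power
    return idw_horizontal(field, lon, lat, day, layer=0, power=power)


def tad_weighted_current(
    field: CurrentField,
    lon: float,
    lat: float,
    day,
    tad: TADHistogram,
    config: AnalysisConfig | None = None,
) -> VelocityVector | None:
    """Vc[TAD]: dive-weighted current over the layers the animal visited.

    Layers with zero weight are never evaluated; a missing current at
    any positively weighted layer makes the whole estimate missing
    (consumed downstream by the gap policy), as does an invalid TAD.
    """
    if not tad.valid:
        return None
    power = (config or AnalysisConfig()).idw_power
    t = field.time_index(day) if not isinstance(day, (int, np.integer)) else day
    u = v = 0.0
    for n in np.nonzero(tad.weights > 0)[0]:
        vc = idw_horizontal(field, lon, lat, t, layer=int(n), power=power)
        if vc is None:
            return None
        u += tad.weights[n] * vc.u
        v += tad.weights[n] * vc.v
    return VelocityVector(u, v)
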