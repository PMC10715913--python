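"""Gap policy and current-corrected track integration.

A corrected track needs a gapless daily swimming-velocity series.
Leading and trailing gap days are trimmed; a track is then rejected if
any interior gap exceeds 48 h (strictly: a 48 h gap is retained) or if
more than 20% of its days are gaps.  Remaining gaps are filled by
linearly interpolating the encountered current between the nearest
valid neighbours and re-deriving Vs = Vg - Vc (or, optionally, by
interpolating Vs directly).  The corrected track integrates Vs with
daily Euler steps in the local metric: the animal's movement in a
motionless ocean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geodesy import local_step
from .types import CorrectedTrack

SECONDS_PER_DAY = 86400.0


def _valid_mask(kin: pd.DataFrame, variant: str) -> np.ndarray:
    col = "ustad" if variant == "tad" else "us0"
    return kin[col].notna().to_numpy()


def apply_gap_policy(
    kin: pd.DataFrame, config: AnalysisConfig | None = None, variant: str = "tad"
) -> tuple[pd.DataFrame | None, dict]:
    """Trim edge gaps, then accept or reject the track.

    Returns (retained frame or None, decision log).  The decision log
    records the trims, the verdict and the reason for any rejection.
    Pure function of the day-validity mask: re-running it on its own
    output changes nothing.
    """
    config = config or AnalysisConfig()
    valid = _valid_mask(kin, variant)
    decision = {"variant": variant, "n_days_in": int(len(kin))}
    if not valid.any():
        decision.update(accepted=False, reason="no valid days")
        return None, decision

    first, last = int(np.argmax(valid)), int(len(valid) - 1 - np.argmax(valid[::-1]))
    decision["trimmed_leading"] = first
    decision["trimmed_trailing"] = int(len(valid) - 1 - last)
    retained = kin.iloc[first : last + 1].reset_index(drop=True)
    valid = valid[first : last + 1]

    # interior gap lengths in days
    gap_len = 0
    max_gap = 0
    for v in valid:
        gap_len = 0 if v else gap_len + 1
        max_gap = max(max_gap, gap_len)
    gap_hours = max_gap * 24.0
    gap_fraction = float((~valid).mean())
    decision.update(
        n_days=int(len(retained)), max_gap_hours=gap_hours, gap_fraction=gap_fraction
    )
    if gap_hours > config.gap_max_hours:
        decision.update(accepted=False, reason=f"gap > {config.gap_max_hours:g} h")
        return None, decision
    if gap_fraction > config.gap_max_fraction:
        decision.update(
            accepted=False, reason=f"> {100 * config.gap_max_fraction:g}% gaps"
        )
        return None, decision
    decision.update(accepted=True, reason=None)
    return retained, decision


def fill_gaps(
    retained: pd.DataFrame, config: AnalysisConfig | None = None, variant: str = "tad"
) -> pd.DataFrame:
    """Return a copy with a gapless swimming-velocity series and a
    ``filled`` flag column."""
    config = config or AnalysisConfig()
    uc, vc = ("uctad", "vctad") if variant == "tad" else ("uc0", "vc0")
    us, vs = ("ustad", "vstad") if variant == "tad" else ("us0", "vs0")
    out = retained.copy()
    valid = out[us].notna().to_numpy()
    assert valid[0] and valid[-1], "edge gaps must have been trimmed by the gap policy"
    out["filled"] = ~valid
    if valid.all():
        return out

    idx = np.arange(len(out))
    if config.gap_fill_mode == "current":
        for c in (uc, vc):
            out[c] = np.interp(idx, idx[valid], out[c].to_numpy()[valid])
        gap_vg_ok = out["ug"].notna().to_numpy()
        fill_from_current = ~valid & gap_vg_ok
        out.loc[fill_from_current, us] = out.loc[fill_from_current, "ug"] - out.loc[fill_from_current, uc]
        out.loc[fill_from_current, vs] = out.loc[fill_from_current, "vg"] - out.loc[fill_from_current, vc]
        # without a ground velocity the re-derivation is impossible;
        # fall back to direct Vs interpolation for those days
        rest = ~valid & ~gap_vg_ok
        if rest.any():
            for c in (us, vs):
                out.loc[rest, c] = np.interp(idx[rest], idx[valid], retained[c].to_numpy()[valid])
    else:  # direct Vs interpolation
        for c in (us, vs):
            out[c] = np.interp(idx, idx[valid], out[c].to_numpy()[valid])
    return out


def integrate_track(
    start_lon: float, start_lat: float, filled: pd.DataFrame, variant: str = "tad",
    animal_id: str = "",
) -> CorrectedTrack:
    """Integrate the daily swimming velocity from the first retained
    midpoint: X(day+1) = X(day) + Vs(day) * 86 400 s."""
    us, vs = ("ustad", "vstad") if variant == "tad" else ("us0", "vs0")
    u = filled[us].to_numpy(dtype=float)
    v = filled[vs].to_numpy(dtype=float)
    if np.isnan(u).any():
        raise ValueError("swimming-velocity series contains gaps; run fill_gaps first")
    lon, lat = float(start_lon), float(start_lat)
    lons, lats = [lon], [lat]
    for i in range(len(u) - 1):
        if abs(lat) > 89.0:
            raise ValueError("corrected track approached a pole")
        lon, lat = local_step(lon, lat, u[i] * SECONDS_PER_DAY, v[i] * SECONDS_PER_DAY)
        lons.append(lon)
        lats.append(lat)
    days = pd.DataFrame(
        {
            "date": filled["date"].to_numpy(),
            "lon": lons,
            "lat": lats,
            "filled": filled["filled"].to_numpy() if "filled" in filled else False,
        }
    )
    return CorrectedTrack(animal_id=animal_id, variant=variant, days=days)


def corrected_track(
    kin: pd.DataFrame,
    config: AnalysisConfig | None = None,
    variant: str = "tad",
    animal_id: str = "",
) -> tuple[CorrectedTrack | None, pd.DataFrame | None, dict]:
    """Gap policy + fill + integration in one call.

    Returns (track or None, the retained/filled kinematics, decision log).
    """
    retained, decision = apply_gap_policy(kin, config, variant)
    if retained is None:
        return None, None, decision
    filled = fill_gaps(retained, config, variant)
    start_lon = filled["lon12"].iat[0]
    start_lat = filled["lat12"].iat[0]
    track = integrate_track(start_lon, start_lat, filled, variant, animal_id)
    return track, filled, decision
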