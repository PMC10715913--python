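"""Track- and cohort-level statistics.

Straightness is net geodesic displacement divided by summed daily
geodesic path length (1 = perfectly straight); speed summaries report
the distribution of the swimming-speed norm with the share of
implausible days above 0.8 m/s; the latitude-banded relative-error
profile localises where surface currents misrepresent the drift of a
diving animal; paired t-tests compare the same segments across the
three track variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .geodesy import geodesic_inverse, path_length

log = logging.getLogger("divecorrect")

VARIANT_COLS = {"tad": ("ustad", "vstad"), "surface": ("us0", "vs0"), "ground": ("ug", "vg")}


def straightness(lons, lats) -> float:
    """Net displacement over path length, in [0, 1]; nan for a
    degenerate (zero-length) path."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if len(lons) < 2:
        raise ValueError("straightness needs at least 2 positions")
    total = path_length(lons, lats)
    if total == 0.0:
        return float("nan")
    net, _ = geodesic_inverse(lons[0], lats[0], lons[-1], lats[-1])
    return min(1.0, net / total)


def speed_summary(
    kin: pd.DataFrame, variant: str = "tad", config: AnalysisConfig | None = None
) -> dict:
    """n, mean, sd, max of the swimming-speed norm plus the share of
    days above the implausible-speed threshold."""
    config = config or AnalysisConfig()
    ucol, vcol = VARIANT_COLS[variant]
    u = kin[ucol].to_numpy(dtype=float)
    v = kin[vcol].to_numpy(dtype=float)
    speed = np.hypot(u, v)
    speed = speed[np.isfinite(speed)]
    if len(speed) == 0:
        log.warning("speed_summary: no valid days for variant %r", variant)
        return {"variant": variant, "n": 0, "mean": np.nan, "sd": np.nan, "max": np.nan,
                "exceedance": np.nan}
    return {
        "variant": variant,
        "n": int(len(speed)),
        "mean": float(speed.mean()),
        "sd": float(speed.std(ddof=1)) if len(speed) > 1 else 0.0,
        "max": float(speed.max()),
        "exceedance": float((speed > config.speed_unrealistic).mean()),
    }


def latitudinal_error_profile(
    kin: pd.DataFrame, band_deg: float = 1.0, benchmark: float = 0.1
) -> pd.DataFrame:
    """Mean +/- sd of the relative error eps per latitude band of the
    daily midpoints; days with undefined eps are excluded."""
    eps = kin["eps"].to_numpy(dtype=float)
    lat = kin["lat12"].to_numpy(dtype=float)
    ok = np.isfinite(eps) & np.isfinite(lat)
    eps, lat = eps[ok], lat[ok]
    if len(eps) == 0:
        return pd.DataFrame(columns=["lat_low", "lat_high", "n", "mean_eps", "sd_eps", "above_benchmark"])
    lo = np.floor(lat.min() / band_deg) * band_deg
    hi = np.ceil(lat.max() / band_deg) * band_deg
    edges = np.arange(lo, hi + band_deg / 2, band_deg)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (lat >= a) & (lat < b)
        if not sel.any():
            continue
        e = eps[sel]
        rows.append(
            {
                "lat_low": float(a),
                "lat_high": float(b),
                "n": int(sel.sum()),
                "mean_eps": float(e.mean()),
                "sd_eps": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
                "above_benchmark": bool(e.mean() > benchmark),
            }
        )
    return pd.DataFrame(rows)


def compare_tracks(segments: list) -> dict:
    """Paired comparison of straightness and heading RMSE across track
    variants on the same valid segments.

    Two-sided paired t-tests: TAD vs surface and TAD vs real.  Fewer
    than two usable segments yields an undefined comparison with a
    warning; exactly two is flagged low-power (1 degree of freedom).
    """
    valid = [s for s in segments if s.valid and s.straightness]
    out = {"n_segments": len(valid)}
    if len(valid) < 2:
        log.warning("compare_tracks: fewer than 2 valid segments; tests undefined")
        out["tests"] = None
        return out
    metrics = {}
    for name in ("tad", "surface", "real"):
        metrics[name] = {
            "S": np.array([s.straightness[name] for s in valid]),
            "rmse": np.array([s.mean_rmse[name] for s in valid]),
        }
    out["mean_S"] = {k: float(np.nanmean(v["S"])) for k, v in metrics.items()}
    out["mean_rmse"] = {k: float(np.nanmean(v["rmse"])) for k, v in metrics.items()}
    tests = {}
    for metric in ("S", "rmse"):
        for other in ("surface", "real"):
            a, b = metrics["tad"][metric], metrics[other][metric]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2 or np.allclose(a[ok], b[ok]):
                t, p = (0.0, 1.0) if ok.sum() >= 2 else (np.nan, np.nan)
            else:
                t, p = stats.ttest_rel(a[ok], b[ok])
            tests[f"{metric}_tad_vs_{other}"] = {
                "t": float(t),
                "p": float(p),
                "n": int(ok.sum()),
                "low_power": bool(ok.sum() <= 2),
            }
    out["tests"] = tests
    return out


def per_track_report(track_results: list) -> pd.DataFrame:
    """One row per track in the shape of the study's segmentation table:
    distances (total and over valid constant-heading segments), number
    of breakpoints (with shallow count), heading changes, breakpoint
    frequency, and mean straightness/RMSE per variant.

    ``track_results`` is a list of dicts as produced by
    CurrentCorrectionResults.report_row().
    """
    if not track_results:
        return pd.DataFrame()
    df = pd.DataFrame(track_results)
    total = {
        "id": "SUM",
        "distance_km": df["distance_km"].sum(),
        "constant_heading_km": df["constant_heading_km"].sum(),
        "nbkps": df["nbkps"].sum(),
        "nbkps_shallow": df["nbkps_shallow"].sum(),
    }
    mean = {
        "id": "MEAN",
        **{
            c: df[c].mean()
            for c in df.columns
            if c.startswith(("S_", "rmse_")) or c in ("distance_km", "constant_heading_km", "nbkps")
        },
    }
    return pd.concat([df, pd.DataFrame([mean, total])], ignore_index=True)


def constant_heading_share(report: pd.DataFrame) -> float:
    """Share (%) of the total distance travelled that falls in valid
    constant-heading segments."""
    sum_row = report[report["id"] == "SUM"]
    if len(sum_row):
        d = float(sum_row["distance_km"].iloc[0])
        c = float(sum_row["constant_heading_km"].iloc[0])
    else:
        d = float(report["distance_km"].sum())
        c = float(report["constant_heading_km"].sum())
    return 100.0 * c / d
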