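"""Readers, writers and tabular summaries for tracks, depth series and
gridded fields.

CSV dialect is fixed (comma separator, '.' decimal, header row).
Timestamps are parsed as ISO-8601 and assumed UTC when unzoned (with a
warning); zoned timestamps are converted to UTC.  NetCDF files are read
and written through xarray (classic NetCDF3).
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd
import xarray as xr

from .geodesy import wrap_lon
from .types import (
    PSY4_LAYER_BOUNDS,
    BathymetryGrid,
    CurrentField,
    DepthSeries,
    RawTrack,
)

log = logging.getLogger("divecorrect")


def _parse_times(raw: pd.Series, path, colname="time") -> pd.Series:
    times = pd.to_datetime(raw, format="ISO8601", errors="coerce", utc=True)
    bad = times.isna() & raw.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise ValueError(f"{path}: unparseable {colname} at line {line}: {raw[bad.idxmax()]!r}")
    if not raw.astype(str).str.contains(r"[+-]\d\d:?\d\d$|Z$", regex=True).all():
        log.warning("%s: unzoned timestamps assumed UTC", path)
    return times.dt.tz_convert("UTC").dt.tz_localize(None)


def _parse_floats(raw: pd.Series, path, colname) -> pd.Series:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: unparseable {colname} at line {line}: {raw[bad.idxmax()]!r}")
    return vals.astype(float)


def read_tracks(path) -> list[RawTrack]:
    """Read one or more tracks from a CSV with columns id,time,lon,lat[,quality]."""
    path = pathlib.Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"id", "time", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["time"] = _parse_times(df["time"], path)
    df["lon"] = _parse_floats(df["lon"], path, "lon")
    df["lat"] = _parse_floats(df["lat"], path, "lat")
    # inputs on [0, 360) are remapped; anything else out of bounds is an error
    if ((df["lon"] < -180) | (df["lon"] >= 360)).any():
        raise ValueError(f"{path}: lon out of range")
    df["lon"] = wrap_lon(df["lon"].to_numpy())
    if ((df["lat"] < -90) | (df["lat"] > 90)).any():
        raise ValueError(f"{path}: lat out of range")

    tracks = []
    for animal_id, sub in df.groupby("id", sort=False):
        sub = sub.sort_values("time", kind="stable")
        dup = sub["time"].duplicated(keep="first")
        if dup.any():
            log.warning("track %s: dropped %d duplicate-timestamp fixes", animal_id, dup.sum())
            sub = sub[~dup]
        if len(sub) < 2:
            raise ValueError(f"{path}: track {animal_id} has fewer than 2 fixes")
        cols = ["time", "lon", "lat"] + (["quality"] if "quality" in sub.columns else [])
        tracks.append(RawTrack(animal_id=str(animal_id), fixes=sub[cols].reset_index(drop=True)))
    if not tracks:
        raise ValueError(f"{path}: no tracks found")
    return tracks


def read_track(path) -> RawTrack:
    """Read a single-animal track CSV (errors if the file mixes ids)."""
    tracks = read_tracks(path)
    if len(tracks) > 1:
        raise ValueError(f"{path}: expected a single animal id, found {len(tracks)}")
    return tracks[0]


def write_tracks(tracks, path) -> None:
    frames = []
    for tr in tracks if isinstance(tracks, (list, tuple)) else [tracks]:
        f = tr.fixes.copy()
        f.insert(0, "id", tr.animal_id)
        frames.append(f)
    pd.concat(frames).to_csv(path, index=False)


def read_depth_series(path) -> list[DepthSeries]:
    path = pathlib.Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"id", "time", "depth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["time"] = _parse_times(df["time"], path)
    df["depth"] = pd.to_numeric(df["depth"], errors="coerce")
    out = []
    for animal_id, sub in df.groupby("id", sort=False):
        sub = sub.sort_values("time", kind="stable").drop_duplicates("time")
        out.append(
            DepthSeries(animal_id=str(animal_id), records=sub[["time", "depth"]].reset_index(drop=True))
        )
    return out


def write_depth_series(series, path) -> None:
    frames = []
    for ds in series if isinstance(series, (list, tuple)) else [series]:
        r = ds.records.copy()
        r.insert(0, "id", ds.animal_id)
        frames.append(r)
    pd.concat(frames).to_csv(path, index=False)


# ---------------------------------------------------------------- NetCDF

_DIM_ALIASES = {
    "time": ("time", "t"),
    "depth": ("depth", "z", "lev", "layer"),
    "lat": ("lat", "latitude", "y"),
    "lon": ("lon", "longitude", "x"),
}


def _find_dim(ds: xr.Dataset, canonical: str) -> str:
    for name in _DIM_ALIASES[canonical]:
        if name in ds.dims:
            return name
    raise ValueError(f"NetCDF file lacks a recognisable '{canonical}' dimension")


def read_current_field(path, expect_psy4_layers: bool = False) -> CurrentField:
    """Read a 4-D current field (time x depth x lat x lon, variables u, v).

    With ``expect_psy4_layers`` the 30 layer bounds must match the
    standard 0-318.1 m table to 0.05 m.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        for var in ("u", "v"):
            if var not in ds:
                raise ValueError(f"{path}: missing variable '{var}'")
        dims = {c: _find_dim(ds, c) for c in ("time", "depth", "lat", "lon")}
        depth = ds[dims["depth"]].values.astype(float)
        if np.any(np.diff(depth) <= 0):
            raise ValueError(f"{path}: depth axis must be strictly increasing")
        if expect_psy4_layers:
            if len(depth) != len(PSY4_LAYER_BOUNDS) or not np.allclose(
                depth, PSY4_LAYER_BOUNDS, atol=0.05
            ):
                raise ValueError(f"{path}: layer bounds do not match the standard 30-layer table")
        u = ds["u"].transpose(dims["time"], dims["depth"], dims["lat"], dims["lon"]).values
        v = ds["v"].transpose(dims["time"], dims["depth"], dims["lat"], dims["lon"]).values
        return CurrentField(
            times=ds[dims["time"]].values.astype("datetime64[ns]"),
            layer_bounds=depth,
            lats=ds[dims["lat"]].values.astype(float),
            lons=ds[dims["lon"]].values.astype(float),
            u=np.asarray(u, dtype=float),
            v=np.asarray(v, dtype=float),
        )


def write_current_field(field: CurrentField, path) -> None:
    ds = xr.Dataset(
        {
            "u": (("time", "depth", "lat", "lon"), field.u),
            "v": (("time", "depth", "lat", "lon"), field.v),
        },
        coords={
            "time": field.times,
            "depth": field.layer_bounds,
            "lat": field.lats,
            "lon": field.lons,
        },
    )
    ds["u"].attrs["units"] = "m s-1"
    ds["v"].attrs["units"] = "m s-1"
    ds["depth"].attrs["positive"] = "down"
    ds.to_netcdf(path, engine="scipy")


def read_bathymetry(path) -> BathymetryGrid:
    """Read a bathymetry grid; the depth variable's ``positive`` attribute
    ("down" default, or "up" for elevation grids) fixes the sign."""
    with xr.open_dataset(path, engine="scipy") as ds:
        name = next((v for v in ("depth", "elevation", "z") if v in ds), None)
        if name is None:
            raise ValueError(f"{path}: no depth/elevation variable")
        dims = {c: _find_dim(ds, c) for c in ("lat", "lon")}
        arr = ds[name].transpose(dims["lat"], dims["lon"]).values.astype(float)
        positive = ds[name].attrs.get("positive", "down" if name == "depth" else "up")
        if positive == "up":
            arr = -arr
        return BathymetryGrid(
            lats=ds[dims["lat"]].values.astype(float),
            lons=ds[dims["lon"]].values.astype(float),
            depth_m=arr,
        )


def write_bathymetry(bathy: BathymetryGrid, path) -> None:
    ds = xr.Dataset(
        {"depth": (("lat", "lon"), bathy.depth_m)},
        coords={"lat": bathy.lats, "lon": bathy.lons},
    )
    ds["depth"].attrs.update(units="m", positive="down")
    ds.to_netcdf(path, engine="scipy")


# ------------------------------------------------------------- summaries

def tag_summary(tracks) -> dict:
    """Deployment summary: track count, mean/sd tag lifetime in whole days
    (overall and per tag model) and group shares in percent.

    Accepts a list of RawTrack (with metadata) or a DataFrame with
    columns ``duration_days`` and optionally ``tag_model``/``group``.
    """
    if isinstance(tracks, pd.DataFrame):
        meta = tracks
    else:
        if not tracks:
            raise ValueError("tag_summary: empty track list")
        meta = pd.DataFrame(
            {
                "duration_days": [t.duration_days if t.duration_days is not None else t.span_days for t in tracks],
                "tag_model": [t.tag_model for t in tracks],
                "group": [t.group for t in tracks],
            }
        )
    if len(meta) == 0:
        raise ValueError("tag_summary: empty input")
    if meta["duration_days"].isna().any():
        raise ValueError("tag_summary: missing durations")

    def _stats(col: pd.Series) -> dict:
        mean = float(col.mean())
        single = len(col) < 2
        sd = 0.0 if single else float(col.std(ddof=1))
        return {
            "n": int(len(col)),
            "mean_days": int(round(mean)),
            "sd_days": int(round(sd)),
            "sd_undefined": single,
        }

    out = {"overall": _stats(meta["duration_days"]), "by_tag_model": {}, "group_shares_pct": {}}
    if "tag_model" in meta and meta["tag_model"].notna().any():
        for model, sub in meta.groupby("tag_model"):
            out["by_tag_model"][str(model)] = _stats(sub["duration_days"])
    if "group" in meta and meta["group"].notna().any():
        shares = meta["group"].value_counts(normalize=True) * 100.0
        out["group_shares_pct"] = {str(k): float(v) for k, v in shares.items()}
    return out


def write_manifest(path, config, seed=None, extra=None) -> None:
    """JSON run manifest: configuration, seed and library versions."""
    import scipy

    from . import __version__

    manifest = {
        "divecorrect": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "xarray": xr.__version__,
        "seed": seed,
        "config": config.to_dict() if hasattr(config, "to_dict") else config,
    }
    if extra:
        manifest.update(extra)
    pathlib.Path(path).write_text(json.dumps(manifest, indent=2, default=str))
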