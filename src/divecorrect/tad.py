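"""Daily time-at-depth (TAD) histograms on the current-model layer bins.

Bin 0 holds the surface (0 m exactly); bin n (n >= 1) holds depths in
the half-open interval (bounds[n-1], bounds[n]].  Depths beyond the
last bound are clamped into the deepest bin and counted.  A day's
histogram is valid when at least ``tad_min_fraction`` of the nominal
288 five-minute records are present (47 records at the 16% default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import (
    N_LAYERS,
    PSY4_LAYER_BOUNDS,
    RECORDS_PER_DAY,
    DepthSeries,
    TADHistogram,
)

log = logging.getLogger("divecorrect")


def bin_index(depth, bounds: np.ndarray = PSY4_LAYER_BOUNDS):
    """Depth bin for a depth in metres (scalar or array).

    Returns (bins, n_clamped): clamped values fell beyond the deepest
    bound and were assigned to the last bin.
    """
    arr = np.asarray(depth, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative depth")
    idx = np.searchsorted(bounds, arr, side="left")
    n_clamped = int(np.count_nonzero(idx > len(bounds) - 1))
    if n_clamped:
        log.warning("%d depth records beyond %.1f m clamped to the deepest bin", n_clamped, bounds[-1])
    idx = np.minimum(idx, len(bounds) - 1)
    if np.isscalar(depth):
        return int(idx), n_clamped
    return idx.astype(int), n_clamped


def build_daily_tad(
    depths: DepthSeries, day, config: AnalysisConfig | None = None,
    bounds: np.ndarray = PSY4_LAYER_BOUNDS,
) -> TADHistogram:
    """Histogram of the day's depth records, normalised to sum to one.

    Records with missing depth are dropped; a day with zero usable
    records gets all-zero weights and ``valid = False``.
    """
    config = config or AnalysisConfig()
    day = pd.Timestamp(day).normalize()
    r = depths.records
    sel = (r["time"] >= day) & (r["time"] < day + pd.Timedelta(days=1))
    vals = r.loc[sel, "depth"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    weights = np.zeros(N_LAYERS)
    n_clamped = 0
    if n > 0:
        idx, n_clamped = bin_index(vals, bounds)
        counts = np.bincount(idx, minlength=N_LAYERS)
        weights = counts / n
    return TADHistogram(
        day=day.date(),
        weights=weights,
        n_records=n,
        valid=n >= config.tad_min_records,
        n_clamped=n_clamped,
    )


def daily_tads(depths: DepthSeries, dates, config: AnalysisConfig | None = None) -> list[TADHistogram]:
    return [build_daily_tad(depths, d, config) for d in dates]


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def subsample_validation(
    full: DepthSeries,
    fractions,
    n_reps: int = 100,
    seed: int = 0,
    metric=total_variation,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """How much does a daily TAD change when thinned to a fraction of
    its records?

    For each fraction, every day of the (near-complete) series is
    randomly thinned ``n_reps`` times and the dissimilarity between the
    thinned and full daily histograms is measured (total-variation
    distance by default).  Supports choosing a minimum-completeness
    criterion from a fully recovered tag.
    """
    config = config or AnalysisConfig()
    fractions = list(fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    r = full.records.dropna(subset=["depth"])
    days = pd.Series(r["time"]).dt.normalize().unique()
    coverage = np.mean([
        ((r["time"] >= d) & (r["time"] < d + pd.Timedelta(days=1))).sum() / RECORDS_PER_DAY
        for d in days
    ])
    if coverage < 0.8:
        raise ValueError("subsample_validation needs >= 80% daily coverage")
    rng = np.random.default_rng(seed)

    full_hists = {d: build_daily_tad(full, d, config) for d in days}
    rows = []
    for frac in fractions:
        dists = []
        for d in days:
            h_full = full_hists[d]
            day_records = r[(r["time"] >= d) & (r["time"] < d + pd.Timedelta(days=1))]
            vals = day_records["depth"].to_numpy(dtype=float)
            n = len(vals)
            k = max(1, int(round(frac * n)))
            for _ in range(n_reps):
                if frac >= 1.0:
                    sub = vals
                else:
                    sub = rng.choice(vals, size=k, replace=False)
                idx, _ = bin_index(sub)
                w = np.bincount(idx, minlength=N_LAYERS) / len(sub)
                dists.append(metric(w, h_full.weights))
        dists = np.asarray(dists)
        rows.append(
            {
                "fraction": frac,
                "mean_dissimilarity": float(dists.mean()),
                "sd_dissimilarity": float(dists.std(ddof=1)) if len(dists) > 1 else 0.0,
                "n": len(dists),
            }
        )
    return pd.DataFrame(rows)
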