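"""Statsmodels-style entry point for the full analysis of one track.

``CurrentCorrection`` is built from the data (raw fixes, depth series,
gridded currents, bathymetry); ``fit()`` runs the pipeline — daily
interpolation, time-at-depth histograms, encountered currents,
swimming-velocity decomposition, gap policy, corrected-track
integration and heading segmentation — and returns a
``CurrentCorrectionResults`` carrying the estimates and diagnostics
with a ``summary()`` table.
"""

from __future__ import annotations

import pathlib
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .corrected import corrected_track
from .geodesy import path_length
from .metrics import speed_summary, straightness
from .preprocess import interpolate_daily, mask_open_ocean
from .segmentation import annotate_shallow, positions_heading, segment_headings
from .tad import daily_tads
from .types import (
    BathymetryGrid,
    CurrentField,
    DepthSeries,
    RawTrack,
    TrackTriplet,
)
from .velocity import assemble_kinematics


class CurrentCorrection:
    """Current-corrected swimming-velocity model for one tracked animal.

    Parameters
    ----------
    track : RawTrack
        Satellite fixes.
    depths : DepthSeries
        5-minute depth records.
    field : CurrentField
        Daily layered current fields covering the track.
    bathymetry : BathymetryGrid, optional
        Needed for open-ocean masking and shallow-water annotation.
    config : AnalysisConfig, optional
    """

    def __init__(
        self,
        track: RawTrack,
        depths: DepthSeries,
        field: CurrentField,
        bathymetry: Optional[BathymetryGrid] = None,
        config: Optional[AnalysisConfig] = None,
        coastal_polygon=None,
    ):
        self.track = track
        self.depths = depths
        self.field = field
        self.bathymetry = bathymetry
        self.config = config or AnalysisConfig()
        self.coastal_polygon = coastal_polygon

    @classmethod
    def from_files(cls, tracks, depths, currents, bathy=None, config=None, **kw):
        from . import io

        track = io.read_track(tracks)
        series = io.read_depth_series(depths)
        matching = [s for s in series if s.animal_id == track.animal_id]
        if not matching:
            raise ValueError(f"no depth series for animal {track.animal_id}")
        field = io.read_current_field(currents)
        bathymetry = io.read_bathymetry(bathy) if bathy else None
        return cls(track, matching[0], field, bathymetry, config, **kw)

    def fit(self) -> "CurrentCorrectionResults":
        cfg = self.config
        daily = interpolate_daily(self.track)
        if self.bathymetry is not None:
            daily = mask_open_ocean(daily, self.bathymetry, self.coastal_polygon, cfg)
        if len(daily) == 0:
            raise ValueError(f"track {self.track.animal_id}: empty open-ocean transect")
        tads = daily_tads(self.depths, daily.days["date"], cfg)
        kin = assemble_kinematics(daily, self.field, tads, cfg)

        corrected = {}
        filled = {}
        decisions = {}
        for variant in ("tad", "surface"):
            trk, fil, dec = corrected_track(kin, cfg, variant, self.track.animal_id)
            corrected[variant] = trk
            filled[variant] = fil
            decisions[variant] = dec

        segmentation = None
        triplet = None
        if corrected["tad"] is not None:
            fil = filled["tad"]
            # align the three variants on the retained days
            dates = fil["date"].to_numpy()
            real_lon = fil["lon12"].to_numpy(dtype=float)
            real_lat = fil["lat12"].to_numpy(dtype=float)
            tad_lon, tad_lat = corrected["tad"].positions()
            if corrected["surface"] is not None and len(corrected["surface"].days) == len(fil):
                surf_lon, surf_lat = corrected["surface"].positions()
            else:
                # integrate the surface variant over the same retained days
                from .corrected import fill_gaps, integrate_track

                sfil = fill_gaps(fil, cfg, "surface") if fil["us0"].isna().any() else fil
                strk = integrate_track(real_lon[0], real_lat[0], sfil, "surface", self.track.animal_id)
                corrected["surface"] = strk
                surf_lon, surf_lat = strk.positions()
            triplet = TrackTriplet(
                dates=dates,
                real=(real_lon, real_lat),
                surface=(surf_lon, surf_lat),
                tad=(tad_lon, tad_lat),
            )
            segmentation = segment_headings(
                fil["ustad"].to_numpy(dtype=float),
                fil["vstad"].to_numpy(dtype=float),
                cfg,
                triplet,
            )
            if self.bathymetry is not None:
                segmentation.breakpoint_flags = annotate_shallow(
                    segmentation.segments,
                    segmentation.breakpoints,
                    real_lon,
                    real_lat,
                    self.bathymetry,
                    cfg,
                )
            else:
                segmentation.breakpoint_flags = [None] * len(segmentation.breakpoints)

        return CurrentCorrectionResults(
            model=self,
            daily=daily,
            tads=tads,
            kinematics=kin,
            corrected=corrected,
            filled=filled,
            gap_decisions=decisions,
            segmentation=segmentation,
            triplet=triplet,
        )


class CurrentCorrectionResults:
    """Fitted pipeline results for one track."""

    def __init__(self, model, daily, tads, kinematics, corrected, filled,
                 gap_decisions, segmentation, triplet):
        self.model = model
        self.daily = daily
        self.tads = tads
        self.kinematics = kinematics
        self.corrected = corrected
        self.filled = filled
        self.gap_decisions = gap_decisions
        self.segmentation = segmentation
        self.triplet = triplet

    @property
    def animal_id(self) -> str:
        return self.model.track.animal_id

    @property
    def coverage(self) -> float:
        """Share of daily positions with a valid TAD-weighted swimming velocity."""
        return self.kinematics.attrs["coverage"]

    def speed_summaries(self) -> pd.DataFrame:
        return pd.DataFrame(
            [speed_summary(self.kinematics, v, self.model.config) for v in ("tad", "surface")]
        )

    def report_row(self) -> dict:
        """The per-track line of the segmentation report."""
        row = {"id": self.animal_id, "n_days": len(self.kinematics), "coverage": self.coverage}
        seg = self.segmentation
        if seg is None or self.triplet is None:
            row.update(
                distance_km=np.nan, constant_heading_km=np.nan, nbkps=np.nan,
                nbkps_shallow=np.nan, rejected=True,
                reject_reason=self.gap_decisions["tad"].get("reason"),
            )
            return row
        real_lon, real_lat = self.triplet.real
        dist_km = path_length(real_lon, real_lat) / 1000.0
        const_km = sum(
            path_length(real_lon[s.start : s.end], real_lat[s.start : s.end]) / 1000.0
            for s in seg.segments
            if s.valid
        )
        flags = getattr(seg, "breakpoint_flags", [None] * len(seg.breakpoints))
        deltas = [s.delta_theta for s in seg.segments if s.delta_theta is not None]
        row.update(
            rejected=False,
            reject_reason=None,
            distance_km=dist_km,
            constant_heading_km=const_km,
            nbkps=len(seg.breakpoints),
            nbkps_shallow=sum(1 for f in flags if f),
            delta_theta=deltas,
            km_per_bkp=const_km / max(1, len(seg.breakpoints)),
        )
        for name in ("tad", "surface", "real"):
            s_vals = [s.straightness[name] for s in seg.segments if s.valid]
            r_vals = [s.mean_rmse[name] for s in seg.segments if s.valid]
            row[f"S_{name}"] = float(np.nanmean(s_vals)) if s_vals else np.nan
            row[f"rmse_{name}"] = float(np.nanmean(r_vals)) if r_vals else np.nan
        return row

    def summary(self) -> str:
        """Readable per-track summary of the fitted analysis."""
        lines = [
            "Current-corrected swimming-velocity analysis",
            "=" * 52,
            f"animal:            {self.animal_id}",
            f"days analysed:     {len(self.kinematics)}",
            f"Vs[TAD] coverage:  {100 * self.coverage:.1f}%",
        ]
        for _, s in self.speed_summaries().iterrows():
            lines.append(
                f"||Vs[{s['variant']}]||:  mean {s['mean']:.3f}  sd {s['sd']:.3f}  "
                f"max {s['max']:.3f} m/s  (>{self.model.config.speed_unrealistic:g} m/s: "
                f"{100 * s['exceedance']:.1f}%)"
            )
        seg = self.segmentation
        if seg is None:
            reason = self.gap_decisions["tad"].get("reason")
            lines.append(f"corrected track:   rejected ({reason})")
        else:
            lines.append(
                f"breakpoints:       {len(seg.breakpoints)} at days {seg.breakpoints}"
                + ("  [no clear elbow]" if seg.elbow_warning else "")
            )
            for i, s in enumerate(seg.segments):
                mark = "valid" if s.valid else "RMSE>=30"
                extra = ""
                if s.straightness:
                    extra = (
                        f"  S(tad/surf/real) "
                        f"{s.straightness['tad']:.2f}/{s.straightness['surface']:.2f}/"
                        f"{s.straightness['real']:.2f}"
                    )
                lines.append(
                    f"  segment {i}: days {s.start}-{s.end - 1}  "
                    f"theta {s.theta_bar:.1f} deg  RMSE {s.rmse:.1f} deg  [{mark}]{extra}"
                )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the per-track CSV outputs into a directory."""
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        aid = self.animal_id
        self.daily.days.to_csv(out / f"{aid}_daily_track.csv", index=False)
        tad_rows = []
        for t in self.tads:
            r = {"date": t.day, "n_records": t.n_records,
                 "completeness": t.completeness, "valid": t.valid}
            r.update({f"w{i:02d}": w for i, w in enumerate(t.weights)})
            tad_rows.append(r)
        pd.DataFrame(tad_rows).to_csv(out / f"{aid}_tad.csv", index=False)
        self.kinematics.to_csv(out / f"{aid}_kinematics.csv", index=False)
        for variant, trk in self.corrected.items():
            if trk is not None:
                trk.days.to_csv(out / f"{aid}_corrected_{variant}.csv", index=False)
        if self.segmentation is not None:
            seg = self.segmentation
            pd.DataFrame(
                {"n": range(len(seg.cost_curve)), "cost": seg.cost_curve}
            ).to_csv(out / f"{aid}_cost_curve.csv", index=False)
            seg_rows = [
                {
                    "start": s.start, "end": s.end, "theta_bar": s.theta_bar,
                    "rmse": s.rmse, "valid": s.valid, "shallow": s.shallow,
                    "delta_theta": s.delta_theta,
                    **{f"S_{k}": v for k, v in s.straightness.items()},
                    **{f"rmse_{k}": v for k, v in s.mean_rmse.items()},
                }
                for s in seg.segments
            ]
            pd.DataFrame(seg_rows).to_csv(out / f"{aid}_segments.csv", index=False)
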