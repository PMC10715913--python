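"""Analysis configuration with the pipeline's thresholds.

Defaults implement the reference protocol: a daily time-at-depth
histogram is trusted from 16% of a day's 5-minute records; corrected
tracks reject interior gaps longer than 48 h or more than 20% missing
days; constant-heading segments are valid below 30 deg circular RMSE;
water shallower than 200 m marks shelf positions.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass
from typing import Optional


@dataclass
class AnalysisConfig:
    tad_min_fraction: float = 0.16      # minimum share of 288 daily depth records
    gap_max_hours: float = 48.0         # interior gaps strictly longer are fatal
    gap_max_fraction: float = 0.20      # max share of gap days per track
    rmse_valid_deg: float = 30.0        # segment validity threshold
    shallow_bathy_m: float = 200.0      # shelf flag threshold
    idw_power: float = 2.0              # inverse-distance weighting exponent
    min_segment_len_days: int = 5
    max_nbkps: int = 10
    kernel_bandwidth_rule: str = "median"   # Gaussian-kernel gamma heuristic
    coastal_consec_days: int = 3        # consecutive shallow days ending the transect
    eps_floor: float = 0.01             # m/s; below this the relative error is undefined
    speed_unrealistic: float = 0.8      # m/s; exceedance threshold in speed summaries
    gap_fill_mode: str = "current"      # interpolate current ("current") or Vs ("vs")
    rng_seed: Optional[int] = None

    def __post_init__(self):
        for name in (
            "tad_min_fraction", "gap_max_hours", "rmse_valid_deg", "shallow_bathy_m",
            "idw_power", "min_segment_len_days", "max_nbkps", "coastal_consec_days",
            "eps_floor", "speed_unrealistic",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tad_min_fraction", "gap_max_fraction"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.gap_fill_mode not in ("current", "vs"):
            raise ValueError("gap_fill_mode must be 'current' or 'vs'")
        if self.kernel_bandwidth_rule != "median":
            raise ValueError("only the 'median' bandwidth rule is implemented")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from YAML or TOML; unknown keys raise."""
        path = pathlib.Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def tad_min_records(self) -> int:
        """Minimum record count for a valid daily histogram (ceil of the
        fraction of a nominal 288-record day)."""
        import math

        from .types import RECORDS_PER_DAY

        return math.ceil(self.tad_min_fraction * RECORDS_PER_DAY)
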