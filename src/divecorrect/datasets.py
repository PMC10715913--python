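"""Published cohort tables for the Reunion Island loggerhead study.

Deployment metadata for the 32 late-juvenile loggerhead turtles
(Caretta caretta) satellite-tagged after rehabilitation and released
from Reunion Island between 2019 and 2022, and the per-track open-ocean
distance summary for the 19 northward migrants whose TAD-corrected
track could be computed.  These small printed tables are inputs for the
cohort-level arithmetic (tag-lifetime statistics, group shares, the
share of distance travelled under a constant heading); they are not
outputs of this package.
"""

from __future__ import annotations

import pandas as pd

_DEPLOYMENTS = [
    # (id, name, group, tag_model, duration_days, avg_depth_pct)
    (1, "Brice", "North", "WC", 219, 44.2),
    (2, "Samson", "North", "WC", 197, 37.3),
    (3, "Tina", "North", "LOTEK", 658, 22.8),
    (4, "Celou", "North", "WC", 340, 56.0),
    (5, "Curieuse", "North", "WC", 250, 46.1),
    (6, "India", "North", "LOTEK", 266, 2.8),
    (7, "Petit Toussaint", "North", "WC", 319, 43.7),
    (8, "Tom", "North", "LOTEK", 105, 4.8),
    (9, "Amayah", "North", "WC", 139, 45.6),
    (10, "Cassandre", "North", "WC", 333, 54.7),
    (11, "Cassie", "North", "WC", 300, 51.2),
    (12, "Davina", "North", "WC", 240, 30.7),
    (13, "Germaine2", "North", "WC", 323, 53.6),
    (14, "Isabelle", "North", "LOTEK", 194, 50.2),
    (15, "Mona", "North", "WC", 181, 21.9),
    (16, "Oulanga", "North", "WC", 210, 23.7),
    (17, "Arthur", "North", "WC", 180, 46.4),
    (18, "Hercule", "North", "WC", 168, 65.5),
    (19, "Jacqueline", "North", "LOTEK", 127, 17.4),
    (20, "Jean-Louis", "North", "WC", 179, 65.3),
    (21, "Lyvan", "North", "WC", 178, 34.6),
    (22, "Maina", "North", "LOTEK", 93, 18.5),
    (23, "Margot", "North", "LOTEK", 144, 14.8),
    (24, "Oriane", "North", "LOTEK", 105, 17.2),
    (25, "Tiago", "North", "WC", 128, 67.2),
    (26, "Fifi", "South", "WC", 68, 41.7),
    (27, "Oscar", "South", "WC", 349, 65.3),
    (28, "Ilona", "unknown", "WC", 66, 96.3),
    (29, "Katty2", "unknown", "LOTEK", 4, 50.7),
    (30, "Tikaf", "unknown", "WC", 19, 53.7),
    (31, "Sylvia", "unknown", "WC", 16, 47.4),
    (32, "Camille", "unknown", "WC", 24, 55.8),
]

_SEGMENT_DISTANCES = [
    # (id, name, distance_km, constant_heading_km, nbkps, nbkps_shallow)
    (1, "Brice", 5410, 3102, 1, 0),
    (2, "Samson", 3521, 3521, 2, 0),
    (3, "Tina", 2443, 2443, 1, 0),
    (4, "Celou", 3936, 3408, 2, 0),
    (5, "Curieuse", 4543, 4543, 2, 0),
    (7, "Petit Toussaint", 3165, 3165, 1, 0),
    (9, "Amayah", 3320, 3320, 1, 0),
    (10, "Cassandre", 4305, 4205, 4, 1),
    (11, "Cassie", 6572, 912, 1, 0),
    (12, "Davina", 4659, 4659, 1, 0),
    (13, "Germaine2", 3673, 3673, 1, 0),
    (14, "Isabelle", 5302, 5302, 1, 0),
    (16, "Oulanga", 3892, 3892, 1, 0),
    (17, "Arthur", 3552, 3552, 1, 0),
    (18, "Hercule", 5148, 3915, 3, 0),
    (20, "Jean-Louis", 3942, 3942, 1, 1),
    (21, "Lyvan", 3519, 3519, 1, 0),
    (22, "Maina", 2806, 2371, 2, 0),
    (25, "Tiago", 3140, 3140, 1, 0),
]


def reunion_deployments() -> pd.DataFrame:
    """Deployment table for the 32 tracked turtles: id, name, group
    (North/South/unknown), tag model, tag lifetime in days, and daily
    average percentage of recovered depth records."""
    return pd.DataFrame(
        _DEPLOYMENTS,
        columns=["id", "name", "group", "tag_model", "duration_days", "avg_depth_pct"],
    )


def open_ocean_segments() -> pd.DataFrame:
    """Open-ocean distance summary for the 19 corrected tracks: total
    distance, distance travelled under a constant heading (segments
    with angular RMSE < 30 deg), and breakpoint counts (total and over
    water shallower than 200 m)."""
    return pd.DataFrame(
        _SEGMENT_DISTANCES,
        columns=["id", "name", "distance_km", "constant_heading_km", "nbkps", "nbkps_shallow"],
    )
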