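"""Kernel change-point detection on daily heading series.

Headings are embedded on the unit circle (cos, sin) so the detector is
wrap-safe, and segment homogeneity is measured by the Gaussian-kernel
cost

    c(a, b] = sum_i k(x_i, x_i) - (1/n) sum_ij k(x_i, x_j),
    k(x, y) = exp(-gamma ||x - y||^2),

with gamma from the median heuristic.  Breakpoints are searched by
greedy binary segmentation (nested solutions, deterministic leftmost
tie-breaking) and the number of breakpoints is chosen at the elbow of
the cost curve: the n maximising Cost(n-1) - Cost(n).  By construction
the rule cannot select "no breakpoint".

Circular statistics (mean heading and angular RMSE) classify segments:
a segment is a valid constant-heading leg when its RMSE is below 30
degrees; high-RMSE segments indicate foraging-like meandering rather
than directed swimming, but their flanking breakpoints are retained.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .config import AnalysisConfig
from .geodesy import geodesic_inverse
from .types import BathymetryGrid, Segment, SegmentationResult

log = logging.getLogger("divecorrect")


# ------------------------------------------------------- circular helpers

def wrap_angle(deg):
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)


def circular_mean(headings_deg) -> float:
    """Mean direction in [0, 360); nan for an empty or fully cancelling set."""
    th = np.radians(np.asarray(headings_deg, dtype=float))
    s, c = np.sin(th).mean(), np.cos(th).mean()
    if s == 0.0 and c == 0.0:
        return float("nan")
    out = math.degrees(math.atan2(s, c)) % 360.0
    return 0.0 if out >= 360.0 else out  # tiny negative angles round to 360


def circular_rmse(headings_deg, mean_deg: float | None = None) -> float:
    """Root-mean-square wrapped deviation (deg) about the circular mean."""
    h = np.asarray(headings_deg, dtype=float)
    if mean_deg is None:
        mean_deg = circular_mean(h)
    res = wrap_angle(h - mean_deg)
    return float(np.sqrt(np.mean(res**2)))


# --------------------------------------------------------- heading series

def heading_series(u, v) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Daily headings and their unit-vector embedding.

    Zero-speed days inherit the previous day's heading (flagged); an
    all-zero series is an error.  Returns (headings_deg, embedding
    (n, 2) of (cos, sin), carried_flags).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    if np.all(speed == 0):
        raise ValueError("all-zero speeds: headings undefined")
    headings = np.degrees(np.arctan2(u, v)) % 360.0
    carried = speed == 0
    # forward fill, then backfill any leading zero-speed run
    last = None
    for i in range(len(headings)):
        if carried[i]:
            if last is not None:
                headings[i] = last
        else:
            last = headings[i]
    first_real = int(np.argmax(~carried))
    headings[:first_real] = headings[first_real]
    th = np.radians(headings)
    embedding = np.column_stack([np.cos(th), np.sin(th)])
    return headings, embedding, carried


# ------------------------------------------------------------ kernel cost

def median_heuristic_gamma(x: np.ndarray) -> float:
    """gamma = 1 / median pairwise squared distance (1.0 if degenerate)."""
    from scipy.spatial.distance import pdist

    if len(x) < 2:
        return 1.0
    d2 = pdist(np.asarray(x, dtype=float)) ** 2
    med = float(np.median(d2))
    if med <= 0:
        return 1.0
    return 1.0 / med


def _gram(x: np.ndarray, gamma: float) -> np.ndarray:
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-gamma * d2)


def kernel_cost(x: np.ndarray, gamma: float | None = None) -> float:
    """Gaussian-kernel cost of one segment (rows of ``x`` are points)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("empty segment")
    if gamma is None:
        gamma = median_heuristic_gamma(x)
    k = _gram(x, gamma)
    return float(np.trace(k) - k.sum() / n)


class _CostCache:
    """O(1) segment costs from a 2-D prefix sum of the Gram matrix."""

    def __init__(self, x: np.ndarray, gamma: float):
        k = _gram(x, gamma)
        self.n = len(x)
        p = np.zeros((self.n + 1, self.n + 1))
        p[1:, 1:] = k.cumsum(axis=0).cumsum(axis=1)
        self.p = p

    def cost(self, a: int, b: int) -> float:
        """Cost of the half-open segment [a, b)."""
        n = b - a
        block = self.p[b, b] - self.p[a, b] - self.p[b, a] + self.p[a, a]
        return n - block / n


def binary_segmentation(
    x: np.ndarray,
    n_bkps: int,
    min_size: int = 5,
    gamma: float | None = None,
) -> tuple[list, np.ndarray]:
    """Greedy nested binary segmentation under the kernel cost.

    Returns (breakpoint_path, cost_curve): ``breakpoint_path[n]`` is the
    sorted breakpoint list after n splits and ``cost_curve[n]`` the total
    cost of that segmentation (``cost_curve[0]`` is the unsegmented
    cost).  Ties are broken towards the leftmost split.  The search may
    stop early when no split respects ``min_size``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = len(x)
    if n_bkps < 1:
        raise ValueError("n_bkps must be >= 1")
    if n < 2 * min_size:
        raise ValueError(f"series of length {n} too short for min segment length {min_size}")
    if gamma is None:
        gamma = median_heuristic_gamma(x)
    cache = _CostCache(x, gamma)

    segments = [(0, n)]
    path = [[]]
    costs = [cache.cost(0, n)]
    for _ in range(n_bkps):
        best = None  # (gain, seg_index, split)
        for si, (a, b) in enumerate(segments):
            if b - a < 2 * min_size:
                continue
            c_ab = cache.cost(a, b)
            for t in range(a + min_size, b - min_size + 1):
                gain = c_ab - cache.cost(a, t) - cache.cost(t, b)
                if best is None or gain > best[0] + 1e-15:
                    best = (gain, si, t)
        if best is None:
            break
        _, si, t = best
        a, b = segments[si]
        segments[si : si + 1] = [(a, t), (t, b)]
        bkps = sorted(path[-1] + [t])
        path.append(bkps)
        costs.append(sum(cache.cost(s, e) for s, e in segments))
    return path, np.asarray(costs)


def select_nbkps(cost_curve: np.ndarray) -> tuple[int, bool]:
    """Elbow rule: argmax_n [Cost(n-1) - Cost(n)], smallest n on ties.

    Returns (n, flat_warning).  A flat curve yields n = 1 with a
    warning; the rule never selects zero breakpoints.
    """
    c = np.asarray(cost_curve, dtype=float)
    if len(c) < 2:
        log.warning("cost curve has no splits; defaulting to 1 breakpoint")
        return 1, True
    drops = c[:-1] - c[1:]
    tol = 1e-9 * max(1.0, abs(c[0]))
    if drops.max() <= tol:
        log.warning("no clear elbow in the cost curve; defaulting to 1 breakpoint")
        return 1, True
    return int(np.argmax(drops > drops.max() - tol) + 1), False


# --------------------------------------------------------- segment stats

def positions_heading(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Day-to-day headings (deg) along a daily position series; nan for
    zero displacement."""
    out = np.full(len(lons) - 1, np.nan)
    for i in range(len(lons) - 1):
        dist, az = geodesic_inverse(lons[i], lats[i], lons[i + 1], lats[i + 1])
        if dist > 0:
            out[i] = az
    return out


def segment_stats(
    headings_deg: np.ndarray,
    breakpoints: list,
    config: AnalysisConfig | None = None,
    triplet=None,
) -> list[Segment]:
    """Per-segment circular mean, angular RMSE, validity, and (when a
    TrackTriplet is supplied) straightness and heading RMSE for each
    track variant over the segment's day range."""
    config = config or AnalysisConfig()
    h = np.asarray(headings_deg, dtype=float)
    edges = [0] + list(breakpoints) + [len(h)]
    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg_h = h[a:b]
        theta = circular_mean(seg_h)
        rmse = circular_rmse(seg_h, theta)
        seg = Segment(
            start=a, end=b, theta_bar=theta, rmse=rmse,
            valid=rmse < config.rmse_valid_deg,
        )
        if triplet is not None:
            from .metrics import straightness

            for name in ("tad", "surface", "real"):
                lons, lats = triplet.variant(name)
                seg.straightness[name] = straightness(lons[a:b], lats[a:b])
                vh = positions_heading(lons[a:b], lats[a:b])
                vh = vh[np.isfinite(vh)]
                seg.mean_rmse[name] = circular_rmse(vh) if len(vh) else float("nan")
        segments.append(seg)
    return segments


def heading_changes(segments: list) -> list[float]:
    """Heading changes between successive valid segments, wrapped to
    (-180, 180].  Invalid segments are skipped; fewer than two valid
    segments yield an empty list."""
    valid = [s for s in segments if s.valid]
    deltas = []
    for prev, nxt in zip(valid[:-1], valid[1:]):
        d = float(wrap_angle(nxt.theta_bar - prev.theta_bar))
        prev.delta_theta = d
        deltas.append(d)
    return deltas


def annotate_shallow(
    segments: list,
    breakpoints: list,
    real_lons: np.ndarray,
    real_lats: np.ndarray,
    bathy: BathymetryGrid,
    config: AnalysisConfig | None = None,
) -> list:
    """Flag breakpoints (and whole segments) sitting over the shelf.

    Each breakpoint day is looked up at the matching-date position on
    the real track; the flag is True when the seafloor there is
    shallower than ``shallow_bathy_m``, None when the position is
    off-grid.  A segment is shallow when every day of it is.
    """
    config = config or AnalysisConfig()

    def _shallow(i: int):
        d = bathy.depth_at(float(real_lons[i]), float(real_lats[i]))
        if not np.isfinite(d):
            return None
        return bool(d < config.shallow_bathy_m)

    flags = [_shallow(b) for b in breakpoints]
    for seg in segments:
        day_flags = [_shallow(i) for i in range(seg.start, seg.end)]
        seg.shallow = (
            None if any(f is None for f in day_flags) else all(day_flags)
        )
    return flags


# ------------------------------------------------------------- high level

def segment_headings(
    u: np.ndarray,
    v: np.ndarray,
    config: AnalysisConfig | None = None,
    triplet=None,
) -> SegmentationResult:
    """Full segmentation of one daily velocity series: embed headings,
    run nested binary segmentation to ``max_nbkps``, pick the elbow and
    compute segment statistics."""
    config = config or AnalysisConfig()
    headings, embedding, _ = heading_series(u, v)
    max_splits = min(config.max_nbkps, len(headings) // config.min_segment_len_days - 1)
    max_splits = max(max_splits, 1)
    path, costs = binary_segmentation(
        embedding, max_splits, min_size=config.min_segment_len_days
    )
    n_bkps, warn = select_nbkps(costs)
    n_bkps = min(n_bkps, len(path) - 1)
    segments = segment_stats(headings, path[n_bkps], config, triplet)
    heading_changes(segments)
    return SegmentationResult(
        n_obs=len(headings),
        cost_curve=costs,
        breakpoint_path=path,
        n_bkps=n_bkps,
        elbow_warning=warn,
        segments=segments,
    )
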