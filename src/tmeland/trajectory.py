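"""Spatial trajectory landscapes and the signed cor_st association score.

The route of tumor progression across a section is modeled as a polyline
through cluster centroids, in a manually chosen cluster order (rooted at
the most normal-like / well-differentiated cluster).  Spots project onto
the polyline within a corridor, giving each spot a normalized position
t ∈ [0, 1] along the trajectory.  Per-signature score profiles over t are
binned and smoothed; runs between trend reversals of the smoothed profile
("inflection points") define candidate TME changes, kept when the run's
slope magnitude clears a per-signature threshold.  Two changes of
different features whose t-intervals overlap form a TME pair, scored by

    cor_st = ±(|s_X| + |s_Y|)

positive when both slopes share a sign (features co-vary along the tumor's
evolutional trajectory), negative when they oppose.  The slope pair
(+0.026, +0.028), for example, yields cor_st = +0.054.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmeland.config import AnalysisConfig
from tmeland.grid import SpotGrid
from tmeland.scoring import ScoreTable


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectoryPath:
    """Polyline through cluster centroids, parameterized by normalized
    arc length t ∈ [0, 1]."""

    cluster_ids: list
    vertices: np.ndarray  # (k, 2) pixel coordinates
    t_vertices: np.ndarray  # (k,) cumulative normalized arc length
    total_length: float

    def reversed(self) -> "TrajectoryPath":
        return TrajectoryPath(
            cluster_ids=list(reversed(self.cluster_ids)),
            vertices=self.vertices[::-1].copy(),
            t_vertices=(1.0 - self.t_vertices[::-1]).copy(),
            total_length=self.total_length,
        )


@dataclass
class ScoreProfile:
    """Binned score profile of one signature along a trajectory."""

    signature: str
    t_centers: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    n_spots: np.ndarray
    window: int


@dataclass
class ChangeSegment:
    """A monotone run of a smoothed profile whose slope clears threshold."""

    signature: str
    t0: float
    t1: float
    value0: float
    value1: float

    @property
    def slope(self) -> float:
        return (self.value1 - self.value0) / (self.t1 - self.t0)

    @property
    def sign(self) -> int:
        return 1 if self.slope > 0 else (-1 if self.slope < 0 else 0)


@dataclass
class TMEPair:
    """Two overlapping TME changes on one trajectory, with cor_st."""

    segment_x: ChangeSegment
    segment_y: ChangeSegment
    overlap: tuple[float, float]

    @property
    def overlap_length(self) -> float:
        return self.overlap[1] - self.overlap[0]

    @property
    def cor_st(self) -> float:
        return cor_st(self.segment_x.slope, self.segment_y.slope)


def build_trajectory(grid: SpotGrid, cluster_order) -> TrajectoryPath:
    """Connect cluster centroids, in the given order, into a trajectory.

    Vertices are mean pixel positions of each cluster's member spots; t is
    cumulative polyline length normalized to [0, 1].
    """
    cluster_order = list(cluster_order)
    if len(cluster_order) < 2:
        raise TrajectoryError("a trajectory needs at least 2 clusters")
    labels = grid.clusters
    pos = grid.positions_px
    centroids = []
    for c in cluster_order:
        mask = (labels == c).to_numpy()
        if not mask.any():
            raise TrajectoryError(f"cluster {c!r} has no spots")
        centroids.append(pos[mask].mean(axis=0))
    v = np.asarray(centroids, dtype=float)
    seg_len = np.linalg.norm(np.diff(v, axis=0), axis=1)
    if np.any(seg_len == 0):
        raise TrajectoryError("coincident consecutive cluster centroids")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    return TrajectoryPath(cluster_order, v, cum / total, float(total))


def project_spots(
    path: TrajectoryPath, grid: SpotGrid, corridor_width: float
) -> pd.DataFrame:
    """Project each spot to its nearest point on the trajectory polyline.

    ``corridor_width`` is in pixels; spots whose perpendicular distance to
    the polyline exceeds it are excluded.  On exact distance ties between
    segments the lower t wins.

    Returns a DataFrame indexed by spot id with columns ``t``,
    ``distance`` and boolean ``included`` (t is NaN when excluded).
    """
    if corridor_width <= 0:
        raise TrajectoryError("corridor_width must be positive")
    p = grid.positions_px  # (n, 2)
    a = path.vertices[:-1]  # (k, 2)
    b = path.vertices[1:]
    ab = b - a
    seg_len2 = (ab**2).sum(axis=1)  # (k,)
    # u: (n, k) clamped projection parameter of each spot on each segment
    diff = p[:, None, :] - a[None, :, :]
    u = np.clip((diff * ab[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    nearest = a[None, :, :] + u[:, :, None] * ab[None, :, :]
    dist = np.linalg.norm(p[:, None, :] - nearest, axis=2)  # (n, k)
    t_seg = (
        path.t_vertices[None, :-1]
        + u * (path.t_vertices[1:] - path.t_vertices[:-1])[None, :]
    )
    dmin = dist.min(axis=1)
    # exact ties between segments resolve to the lowest t
    tie = dist <= dmin[:, None]
    t = np.where(tie, t_seg, np.inf).min(axis=1)
    included = dmin <= corridor_width
    t = np.where(included, t, np.nan)
    return pd.DataFrame(
        {"t": t, "distance": dmin, "included": included}, index=grid.spot_ids
    )


def extract_profile(
    scores: ScoreTable | pd.DataFrame,
    projections: pd.DataFrame,
    n_bins: int = 100,
    window: int = 5,
) -> dict[str, ScoreProfile]:
    """Bin per-spot scores along t and smooth with a centered moving average.

    Bins partition [0, 1] into ``n_bins`` equal intervals; a bin's raw
    value is the mean score of the spots projected into it.  Empty bins
    are filled by linear interpolation between their non-empty neighbors
    (constant extension at the ends).  At the profile edges the moving
    average shrinks symmetrically to the available bins, so a window of 1
    is the identity and constants are preserved exactly.

    Requires at least half the bins to be non-empty.
    """
    if window < 1 or window % 2 == 0:
        raise TrajectoryError("window must be a positive odd integer")
    table = scores.scores if isinstance(scores, ScoreTable) else scores
    t = projections["t"].reindex(table.index).to_numpy(dtype=float)
    ok = np.isfinite(t)
    if not ok.any():
        raise TrajectoryError("no spots project onto the trajectory")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    bin_idx = np.clip(np.digitize(t[ok], edges) - 1, 0, n_bins - 1)
    n_spots = np.bincount(bin_idx, minlength=n_bins)
    n_nonempty = int((n_spots > 0).sum())
    if n_nonempty == 0:
        raise TrajectoryError("all trajectory bins are empty")
    if n_nonempty < n_bins / 2:
        raise TrajectoryError(
            f"only {n_nonempty}/{n_bins} trajectory bins contain spots; "
            "widen the corridor or reduce n_bins"
        )
    half = window // 2
    profiles = {}
    for sig in table.columns:
        vals = table[sig].to_numpy(dtype=float)[ok]
        sums = np.bincount(bin_idx, weights=vals, minlength=n_bins)
        raw = np.full(n_bins, np.nan)
        nz = n_spots > 0
        raw[nz] = sums[nz] / n_spots[nz]
        filled = raw.copy()
        if (~nz).any():
            filled[~nz] = np.interp(centers[~nz], centers[nz], raw[nz])
        smoothed = np.array(
            [
                filled[max(0, i - half) : min(n_bins, i + half + 1)].mean()
                for i in range(n_bins)
            ]
        )
        profiles[sig] = ScoreProfile(sig, centers, filled, smoothed, n_spots, window)
    return profiles


def find_change_segments(
    profile: ScoreProfile, slope_threshold: float
) -> list[ChangeSegment]:
    """Extract monotone runs between inflection points of the smoothed
    profile and keep those with |slope| >= slope_threshold.

    Inflection points are trend reversals: bins where the sign of the
    smoothed first difference changes (including flat-to-trending
    transitions; differences below a relative tolerance count as flat).
    """
    v = profile.smoothed
    t = profile.t_centers
    if len(v) < 2:
        return []
    d = np.diff(v)
    scale = np.ptp(v)
    eps = 1e-9 * (scale if scale > 0 else 1.0)
    sign = np.where(d > eps, 1, np.where(d < -eps, -1, 0))
    breaks = [0]
    for i in range(1, len(sign)):
        if sign[i] != sign[i - 1]:
            breaks.append(i)
    breaks.append(len(v) - 1)
    breaks = sorted(set(breaks))
    segments = []
    for b0, b1 in zip(breaks[:-1], breaks[1:]):
        if b1 <= b0:
            continue
        seg = ChangeSegment(profile.signature, t[b0], t[b1], v[b0], v[b1])
        if abs(seg.slope) >= slope_threshold:
            segments.append(seg)
    return segments


def pair_changes(segments: list[ChangeSegment]) -> list[TMEPair]:
    """Pair TME changes of different features whose t-intervals overlap.

    Overlaps of zero length (touching intervals) do not pair.  Every
    overlapping combination of segments from two distinct features yields
    one pair.
    """
    pairs = []
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            sx, sy = segments[i], segments[j]
            if sx.signature == sy.signature:
                continue
            lo = max(sx.t0, sy.t0)
            hi = min(sx.t1, sy.t1)
            if hi > lo:
                if sy.signature < sx.signature:
                    sx, sy = sy, sx
                pairs.append(TMEPair(sx, sy, (lo, hi)))
    return pairs


def cor_st(slope_x, slope_y=None) -> float:
    """Signed association score of a TME pair.

    Magnitude is the sum of the absolute slopes; the sign is positive when
    the two slopes agree in direction and negative when they oppose.
    Accepts either a :class:`TMEPair` or the two slopes.
    """
    if slope_y is None:
        pair: TMEPair = slope_x
        slope_x, slope_y = pair.segment_x.slope, pair.segment_y.slope
    magnitude = abs(slope_x) + abs(slope_y)
    return magnitude if slope_x * slope_y > 0 else -magnitude


def dominant_pair(
    pairs: list[TMEPair], feature_x: str, feature_y: str
) -> TMEPair | None:
    """The headline association for a feature pair: among all TME pairs of
    the two named features, the one spanning the longest overlap of the
    trajectory (ties by |cor_st|, then lower t)."""
    want = {feature_x, feature_y}
    cands = [
        p
        for p in pairs
        if {p.segment_x.signature, p.segment_y.signature} == want
    ]
    if not cands:
        return None
    return max(
        cands, key=lambda p: (p.overlap_length, abs(p.cor_st), -p.overlap[0])
    )


def aggregate_pairs(
    pairs_by_specimen: dict[str, list[TMEPair]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize TME pairs across trajectories/specimens.

    Returns ``(full, summary)``: ``full`` has one row per pair occurrence
    with its specimen and cor_st contribution; ``summary`` aggregates per
    unordered feature pair, summing contributions, and flags pairs whose
    cor_st sign is consistent across every trajectory where they occur.
    The consistent subset mirrors the keep-only-reproducible-pairs display
    rule.
    """
    if not pairs_by_specimen:
        raise TrajectoryError("no trajectories analyzed")
    rows = []
    for specimen, pairs in pairs_by_specimen.items():
        for p in pairs:
            fx, fy = sorted((p.segment_x.signature, p.segment_y.signature))
            rows.append(
                {
                    "feature_x": fx,
                    "feature_y": fy,
                    "specimen": specimen,
                    "cor_st": p.cor_st,
                    "overlap_t0": p.overlap[0],
                    "overlap_t1": p.overlap[1],
                    "overlap_length": p.overlap_length,
                }
            )
    full = pd.DataFrame(
        rows,
        columns=[
            "feature_x", "feature_y", "specimen", "cor_st",
            "overlap_t0", "overlap_t1", "overlap_length",
        ],
    )
    if full.empty:
        summary = pd.DataFrame(
            columns=["feature_x", "feature_y", "cor_st_sum", "n_trajectories", "consistent"]
        )
        return full, summary
    g = full.groupby(["feature_x", "feature_y"])
    summary = g.agg(
        cor_st_sum=("cor_st", "sum"),
        n_trajectories=("specimen", "nunique"),
    ).reset_index()
    signs = g["cor_st"].agg(lambda s: len(set(np.sign(s))) == 1)
    summary["consistent"] = signs.to_numpy()
    return full, summary
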