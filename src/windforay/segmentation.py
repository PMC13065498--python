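"""Splitting fix sequences at the home-range boundary and track metrics.

Whenever an individual exits the 95% home-range isopleth, the contiguous
run of outside fixes up to re-entry forms one *excursion track*.  Five
metrics summarise each track and feed the movement-type clustering:

* ``median_step_km`` — median displacement between consecutive fixes
  (including the virtual entry step from the last inside fix, if any);
* ``median_direction_deg`` — mean heading of the steps, degrees
  clockwise from North (circular mean by default; a circular-median
  variant is available via ``direction_method="median"``);
* ``max_distance_km`` — Euclidean distance from the farthest fix to the
  home-range polygon (zero on the boundary);
* ``duration_h`` — elapsed clock time between the first and last outside
  fix (boundary crossings are not interpolated);
* ``straightness`` — ``max_distance_km`` divided by total path length,
  clipped to (0, 1]; 1 means a perfectly direct out-and-back leg.

Runs truncated by the start or end of the data never observed a
boundary crossing on one side; they are flagged ``complete=False`` and
excluded from clustering so censored durations do not bias the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon

LABELS = ("SRM", "MRM", "LRM")


@dataclass
class ExcursionTrack:
    """One contiguous extra-home-range run of fixes."""

    individual_id: str
    fix_index: np.ndarray          # positional indices into the individual's fixes
    start: pd.Timestamp
    end: pd.Timestamp
    complete: bool
    median_step_km: float = np.nan
    median_direction_deg: float = np.nan
    max_distance_km: float = np.nan
    duration_h: float = np.nan
    straightness: float = np.nan
    metric_complete: bool = True
    cluster: int = -1
    label: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def n_fixes(self) -> int:
        return len(self.fix_index)


def label_inside(fixes: pd.DataFrame, polygon: Polygon | MultiPolygon) -> np.ndarray:
    """Boolean per-fix point-in-polygon test; boundary counts as inside."""
    import shapely

    return shapely.intersects_xy(
        polygon,
        fixes["x_km"].to_numpy(dtype=float),
        fixes["y_km"].to_numpy(dtype=float),
    )


def extract_excursions(fixes: pd.DataFrame, inside: np.ndarray) -> list[ExcursionTrack]:
    """Maximal runs of outside fixes, flagged complete iff flanked inside.

    ``fixes`` must belong to a single individual and be time-sorted.
    """
    inside = np.asarray(inside, dtype=bool)
    if len(inside) != len(fixes):
        raise ValueError("inside flags must align with fixes")
    tracks: list[ExcursionTrack] = []
    n = len(fixes)
    ts = pd.to_datetime(fixes["timestamp"]).reset_index(drop=True)
    ind = str(fixes["individual_id"].iloc[0]) if n else ""
    i = 0
    while i < n:
        if inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not inside[j + 1]:
            j += 1
        complete = (i > 0) and (j < n - 1)
        tracks.append(
            ExcursionTrack(
                individual_id=ind,
                fix_index=np.arange(i, j + 1),
                start=ts[i],
                end=ts[j],
                complete=complete,
            )
        )
        i = j + 1
    return tracks


def _heading_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Step headings in degrees clockwise from North."""
    return np.mod(np.degrees(np.arctan2(dx, dy)), 360.0)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    return float(np.mod(np.degrees(np.arctan2(s, c)), 360.0))


def circular_median_deg(angles_deg: np.ndarray) -> float:
    """Minimiser of mean arc distance over the sample angles (ties: smallest)."""
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    diffs = np.abs(a[None, :] - a[:, None])
    arc = np.minimum(diffs, 360.0 - diffs)
    cost = arc.mean(axis=1)
    best = np.flatnonzero(cost == cost.min())
    return float(a[best].min())


def track_metrics(
    track: ExcursionTrack,
    fixes: pd.DataFrame,
    polygon: Polygon | MultiPolygon,
    direction_method: str = "mean",
) -> ExcursionTrack:
    """Fill the five movement metrics of one excursion track in place.

    Steps are consecutive-fix displacement vectors, prepended with the
    virtual entry step from the last inside fix when one exists.  A
    single-fix run with no inside neighbour has no step, so step-based
    metrics are undefined and the track is flagged metric-incomplete.
    """
    idx = track.fix_index
    pts = fixes[["x_km", "y_km"]].to_numpy(dtype=float)[idx]
    ts = pd.to_datetime(fixes["timestamp"]).reset_index(drop=True)

    entry = None
    if idx[0] > 0:
        entry = fixes[["x_km", "y_km"]].to_numpy(dtype=float)[idx[0] - 1]
    path = pts if entry is None else np.vstack([entry, pts])
    if len(path) < 2:
        track.metric_complete = False
        track.duration_h = 0.0
        track.max_distance_km = float(polygon.boundary.distance(Point(pts[0])))
        return track

    steps = np.diff(path, axis=0)
    lens = np.hypot(steps[:, 0], steps[:, 1])
    headings = _heading_deg(steps[:, 0], steps[:, 1])

    import shapely

    inside_pts = shapely.intersects_xy(polygon, pts[:, 0], pts[:, 1])
    dists = np.where(inside_pts, 0.0,
                     shapely.distance(polygon.boundary,
                                      shapely.points(pts[:, 0], pts[:, 1])))
    total_len = float(lens.sum())
    d_max = float(dists.max())

    track.median_step_km = float(np.median(lens))
    if direction_method == "median":
        track.median_direction_deg = circular_median_deg(headings)
    else:
        track.median_direction_deg = circular_mean_deg(headings)
    track.max_distance_km = d_max
    track.duration_h = float((ts[idx[-1]] - ts[idx[0]]).total_seconds() / 3600.0)
    if total_len <= 0:
        track.metric_complete = False
    else:
        track.straightness = float(np.clip(d_max / total_len, np.finfo(float).tiny, 1.0))
    return track


def segment_individual(
    fixes: pd.DataFrame,
    polygon: Polygon | MultiPolygon,
    direction_method: str = "mean",
) -> tuple[list[ExcursionTrack], np.ndarray]:
    """Label fixes in/out, extract excursions and compute their metrics."""
    inside = label_inside(fixes, polygon)
    tracks = extract_excursions(fixes, inside)
    for tr in tracks:
        track_metrics(tr, fixes, polygon, direction_method)
    return tracks, inside


def tracks_to_frame(tracks: list[ExcursionTrack]) -> pd.DataFrame:
    """One row per excursion track with the five metrics and flags."""
    rows = []
    for k, tr in enumerate(tracks):
        rows.append(
            {
                "track_id": k,
                "individual_id": tr.individual_id,
                "n_fixes": tr.n_fixes,
                "start": tr.start,
                "end": tr.end,
                "complete": tr.complete,
                "metric_complete": tr.metric_complete,
                "median_step_km": tr.median_step_km,
                "median_direction_deg": tr.median_direction_deg,
                "max_distance_km": tr.max_distance_km,
                "duration_h": tr.duration_h,
                "straightness": tr.straightness,
                "cluster": tr.cluster,
                "label": tr.label,
            }
        )
    return pd.DataFrame(rows)


def label_fixes(
    fixes: pd.DataFrame,
    tracks: list[ExcursionTrack],
    inside: np.ndarray,
) -> np.ndarray:
    """Per-fix movement label in {SRM, MRM, LRM}.

    Fixes inside the home range are SRM.  Fixes of clustered (complete,
    metric-complete) tracks inherit the track label.  Fixes of truncated
    or metric-incomplete tracks are labelled by the nearest labelled
    track in metric space when the track has at least 2 fixes, else SRM.
    Labels therefore partition all fixes.
    """
    labels = np.array(["SRM"] * len(fixes), dtype=object)
    clustered = [t for t in tracks if t.label in ("MRM", "LRM")]
    feats = None
    if clustered:
        feats = np.array([[t.median_step_km, t.max_distance_km, t.duration_h]
                          for t in clustered])
        mu, sd = feats.mean(axis=0), feats.std(axis=0)
        sd[sd == 0] = 1.0
        feats = (feats - mu) / sd
    for t in tracks:
        if t.label in ("MRM", "LRM"):
            labels[t.fix_index] = t.label
        elif t.complete and t.metric_complete:
            raise ValueError("complete track without a cluster label")
        elif t.n_fixes >= 2 and clustered and np.isfinite(t.duration_h):
            v = (np.array([t.median_step_km if np.isfinite(t.median_step_km) else 0.0,
                           t.max_distance_km, t.duration_h]) - mu) / sd
            nearest = int(np.argmin(((feats - v) ** 2).sum(axis=1)))
            labels[t.fix_index] = clustered[nearest].label
    return labels
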