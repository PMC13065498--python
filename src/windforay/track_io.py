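"""Reading, writing and screening of GPS fix tables.

A *fix* is one timestamped GPS location of one tagged individual.  Fix
tables are Movebank-like CSV files with at least the columns
``individual_id``, ``timestamp``, ``x_km`` and ``y_km``; optional ``lon``
and ``lat`` columns are carried through untouched.  Internally all
geometry is planar, in kilometres.

Screening implements two data-quality rules applied to the tracking data
before home-range estimation: offshore fixes further than 5 km from the
coastline polygon are treated as implausible and removed, and individuals
tracked for less than 300 days are dropped so that every retained track
covers a full seasonal cycle.

The module also packages a per-individual summary table of the study
population (20 released Griffon Vultures: total GPS locations and the
number of locations in medium- and long-range movements) used as an
arithmetic fixture by the test-suite and the acceptance script.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

#: Columns a fix table must provide.
REQUIRED_COLUMNS = ("individual_id", "timestamp", "x_km", "y_km")

#: Expected number of individuals in the packaged summary table.
N_STUDY_INDIVIDUALS = 20


class SchemaError(ValueError):
    """A fix table is missing a required column."""


class FixtureIntegrityError(ValueError):
    """The packaged summary table failed an integrity check."""


def read_fixes(path: str | Path) -> pd.DataFrame:
    """Read a fix table from CSV.

    The result is sorted by ``(individual_id, timestamp)``; duplicate
    ``(individual_id, timestamp)`` rows are collapsed to the first
    occurrence with the number of dropped rows logged.  A derived
    ``source_interval`` column holds minutes since the previous fix of
    the same individual (NaN for the first fix).

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValueError
        If a timestamp cannot be parsed (the offending line is named).
    """
    frame = pd.read_csv(path)
    return _normalise_fixes(frame, source=str(path))


def _normalise_fixes(frame: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"fix table {source!r} is missing required column {col!r}")
    parsed = pd.to_datetime(frame["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & frame["timestamp"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {frame['timestamp'].iloc[row]!r} "
            f"in {source!r} at data row {row + 1}"
        )
    out = frame.copy()
    out["timestamp"] = parsed
    out = out.sort_values(["individual_id", "timestamp"], kind="mergesort")
    n_before = len(out)
    out = out.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    dropped = n_before - len(out)
    if dropped:
        logger.info("collapsed %d duplicate (individual, timestamp) fixes", dropped)
    out = out.reset_index(drop=True)
    dt = out.groupby("individual_id", sort=False)["timestamp"].diff()
    out["source_interval"] = dt.dt.total_seconds() / 60.0
    return out


def write_fixes(fixes: pd.DataFrame, path: str | Path) -> None:
    """Write a fix table to CSV with ISO-8601 UTC timestamps."""
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def filter_offshore(
    fixes: pd.DataFrame,
    coast_polygon: BaseGeometry,
    max_km: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove implausible offshore fixes.

    A fix is removed iff it lies outside ``coast_polygon`` (the land
    polygon, planar km coordinates) *and* its distance to the polygon
    exceeds ``max_km`` (strictly).  Fixes on the boundary or within
    ``max_km`` seaward are kept.

    Returns ``(kept, removed)``; the two frames partition the input.
    """
    import shapely

    if not coast_polygon.is_valid:
        raise ValueError("invalid coastline polygon")
    if len(fixes):
        x = fixes["x_km"].to_numpy(dtype=float)
        y = fixes["y_km"].to_numpy(dtype=float)
        onshore = shapely.intersects_xy(coast_polygon, x, y)
        offshore = ~onshore
        if offshore.any():
            pts = shapely.points(x[offshore], y[offshore])
            dist = shapely.distance(coast_polygon, pts)
            offshore[np.flatnonzero(offshore)] = dist > max_km
    else:
        offshore = np.zeros(0, dtype=bool)
    kept = fixes.loc[~offshore].reset_index(drop=True)
    removed = fixes.loc[offshore].reset_index(drop=True)
    logger.info("offshore screen: removed %d of %d fixes (> %.1f km from coast)",
                len(removed), len(fixes), max_km)
    return kept, removed


def filter_min_duration(fixes: pd.DataFrame, min_days: float = 300.0) -> pd.DataFrame:
    """Drop individuals whose tracking span is below ``min_days``.

    The span is last minus first timestamp; individuals with span
    strictly less than ``min_days`` are removed entirely.
    """
    if fixes.empty:
        return fixes.reset_index(drop=True)
    span = fixes.groupby("individual_id")["timestamp"].agg(lambda s: s.max() - s.min())
    keep_ids = span.index[span >= pd.Timedelta(days=min_days)]
    out = fixes[fixes["individual_id"].isin(keep_ids)].reset_index(drop=True)
    logger.info("duration screen: kept %d of %d individuals (>= %.0f days)",
                len(keep_ids), span.size, min_days)
    return out


def load_study_table() -> pd.DataFrame:
    """Load the packaged per-individual study summary table."""
    with resources.files("windforay.data").joinpath("study_individuals.csv").open("rb") as fh:
        fixture = pd.read_csv(fh)
    if len(fixture) != N_STUDY_INDIVIDUALS:
        raise FixtureIntegrityError(
            f"summary table must have {N_STUDY_INDIVIDUALS} rows, found {len(fixture)}"
        )
    if (fixture[["gps_locations", "mrm_locations", "lrm_locations"]] < 0).any().any():
        raise FixtureIntegrityError("summary table contains negative counts")
    return fixture


def study_totals(fixture: pd.DataFrame | None = None) -> dict[str, float]:
    """Column totals of the study summary table.

    Returns total GPS locations, total MRM and LRM locations, and the
    implied percentage of short-range (within-home-range) locations,
    ``100 * (total - mrm - lrm) / total`` rounded to one decimal.
    """
    if fixture is None:
        fixture = load_study_table()
    total = int(fixture["gps_locations"].sum())
    mrm = int(fixture["mrm_locations"].sum())
    lrm = int(fixture["lrm_locations"].sum())
    if total == 0:
        raise FixtureIntegrityError("total GPS location count is zero; SRM share undefined")
    srm_pct = round(100.0 * (total - mrm - lrm) / total, 1)
    return {"total_gps": total, "total_mrm": mrm, "total_lrm": lrm, "srm_pct": srm_pct}
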