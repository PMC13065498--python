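"""Joining fixes to gridded hourly weather and deriving wind covariates.

Weather grids follow an ERA5-like layout: an :class:`xarray.Dataset` with
dimensions ``(time, y, x)`` and variables ``u100`` / ``v100`` (eastward /
northward wind components at 100 m, in m/s) and ``ssrd_flux`` (surface
downward short-wave radiation flux, W/m2).  Spatial coordinates are
planar kilometres on a regular ~10 km lattice; ``time`` is hourly UTC.

Wind speed is converted to km/h for compatibility with Beaufort-scale
thresholds; wind direction uses the meteorological convention, i.e. the
compass bearing the wind blows *from* (0 deg = from North, 90 = from
East).  The Mistral quadrant is therefore around 315 deg and the Sirocco
around 135 deg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

MS_TO_KMH = 3.6


def wind_from_uv(u, v):
    """Convert wind components to (speed, meteorological direction).

    Parameters
    ----------
    u, v : array-like
        Eastward and northward wind components in m/s.

    Returns
    -------
    speed_kmh : ndarray
        ``3.6 * sqrt(u**2 + v**2)``.
    direction_deg : ndarray
        Bearing the wind blows from, degrees clockwise from North in
        ``[0, 360)``.  Calm air (``u == v == 0``) maps to 0 by
        convention; use :func:`calm_mask` to flag it.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = MS_TO_KMH * np.hypot(u, v)
    direction = np.mod(np.degrees(np.arctan2(u, v)) + 180.0, 360.0)
    direction = np.where(speed == 0.0, 0.0, direction)
    return speed, direction


def uv_from_wind(speed_kmh, direction_deg):
    """Inverse of :func:`wind_from_uv` (speed km/h, FROM-direction deg)."""
    speed_ms = np.asarray(speed_kmh, dtype=float) / MS_TO_KMH
    theta = np.radians(np.asarray(direction_deg, dtype=float) - 180.0)
    return speed_ms * np.sin(theta), speed_ms * np.cos(theta)


def calm_mask(u, v):
    """True where the wind vector is exactly zero (direction undefined)."""
    return (np.asarray(u) == 0.0) & (np.asarray(v) == 0.0)


def _nearest_hour_index(times: np.ndarray, grid_times: np.ndarray) -> np.ndarray:
    """Index of the nearest grid hour per fix; ties go to the earlier hour."""
    gt = grid_times.astype("datetime64[s]").astype("int64")
    ft = times.astype("datetime64[s]").astype("int64")
    pos = np.searchsorted(gt, ft)
    lo = np.clip(pos - 1, 0, len(gt) - 1)
    hi = np.clip(pos, 0, len(gt) - 1)
    d_lo = np.abs(ft - gt[lo])
    d_hi = np.abs(ft - gt[hi])
    # earlier wins on an exact tie
    return np.where(d_hi < d_lo, hi, lo)


def annotate(fixes: pd.DataFrame, weather: xr.Dataset) -> pd.DataFrame:
    """Join each fix to its nearest weather-grid cell and hour.

    Spatial matching is nearest-neighbour on the (x, y) lattice and
    temporal matching nearest hour (ties resolved to the earlier hour);
    no interpolation is performed, matching extraction of reanalysis
    values at the native ~10 km scale.  Fixes outside the grid's spatial
    or temporal coverage are flagged ``weather_missing`` and get NaN
    covariates; their count is logged.

    Adds columns ``u100``, ``v100``, ``radiation_wm2``, ``wind_kmh``,
    ``wind_dir_deg``, ``calm_flag`` and ``weather_missing``.
    """
    gx = np.asarray(weather["x"].values, dtype=float)
    gy = np.asarray(weather["y"].values, dtype=float)
    gt = np.asarray(weather["time"].values)

    fx = fixes["x_km"].to_numpy(dtype=float)
    fy = fixes["y_km"].to_numpy(dtype=float)
    ft = (pd.to_datetime(fixes["timestamp"], utc=True).dt.tz_localize(None)
          .to_numpy().astype("datetime64[s]"))

    def nearest(grid: np.ndarray, vals: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(grid, vals)
        lo = np.clip(pos - 1, 0, len(grid) - 1)
        hi = np.clip(pos, 0, len(grid) - 1)
        return np.where(np.abs(grid[hi] - vals) < np.abs(vals - grid[lo]), hi, lo)

    ix = nearest(gx, fx)
    iy = nearest(gy, fy)
    it = _nearest_hour_index(ft, gt)

    half_dx = np.median(np.diff(gx)) / 2 if len(gx) > 1 else np.inf
    half_dy = np.median(np.diff(gy)) / 2 if len(gy) > 1 else np.inf
    missing = (
        (fx < gx[0] - half_dx) | (fx > gx[-1] + half_dx)
        | (fy < gy[0] - half_dy) | (fy > gy[-1] + half_dy)
        | (ft < gt[0] - np.timedelta64(30, "m")) | (ft > gt[-1] + np.timedelta64(30, "m"))
    )
    if missing.all() and len(fixes):
        raise ValueError("weather grid is entirely disjoint from the fixes")

    u = weather["u100"].values[it, iy, ix]
    v = weather["v100"].values[it, iy, ix]
    rad = weather["ssrd_flux"].values[it, iy, ix]
    speed, direction = wind_from_uv(u, v)

    out = fixes.copy()
    out["u100"] = np.where(missing, np.nan, u)
    out["v100"] = np.where(missing, np.nan, v)
    out["radiation_wm2"] = np.where(missing, np.nan, rad)
    out["wind_kmh"] = np.where(missing, np.nan, speed)
    out["wind_dir_deg"] = np.where(missing, np.nan, direction)
    out["calm_flag"] = calm_mask(u, v) & ~missing
    out["weather_missing"] = missing
    if missing.any():
        logger.info("weather join: %d fixes outside grid coverage flagged", int(missing.sum()))
    return out


def weather_to_tidy(weather: xr.Dataset) -> pd.DataFrame:
    """Flatten a weather grid to tidy long format (time, x, y, u, v, rad)."""
    df = weather.to_dataframe().reset_index()
    return df.rename(columns={"ssrd_flux": "rad", "u100": "u", "v100": "v"})


def weather_from_tidy(df: pd.DataFrame) -> xr.Dataset:
    """Rebuild a (time, y, x) weather grid from tidy long format."""
    pivot = df.set_index(["time", "y", "x"]).to_xarray()
    return pivot.rename({"u": "u100", "v": "v100", "rad": "ssrd_flux"})
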