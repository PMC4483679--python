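"""Station observations -> daily regional weather series.

Weather stations report point observations; mortality is counted per
administrative region. The bridge is the classic GIS pair: inverse-distance-
weighted (IDW) interpolation of each day's station field to the centroids of
a regular lon/lat grid, followed by zonal estimation — the unweighted mean of
the interpolated values over the grid cells belonging to each region.

Distances are great-circle (haversine, km), appropriate for lon/lat station
coordinates at sub-continental extent. The IDW power defaults to 2 and all
stations contribute to every cell; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # optional: only needed when rasterizing GeoJSON polygons
    from shapely.geometry import Point, shape
except ImportError:  # pragma: no cover
    shape = None

__all__ = [
    "Grid",
    "RegionMask",
    "haversine_km",
    "idw_interpolate",
    "zonal_mean",
    "build_region_series",
    "rasterize_polygon",
    "MissingDataError",
]

EARTH_RADIUS_KM = 6371.0088

WEATHER_VARS = ("tmean", "tmax", "tmin", "rh")


class MissingDataError(ValueError):
    """All stations missing for a date, or a date gap in the series."""


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat grid defined by its origin (lower-left corner),
    cell size in degrees and cell counts. Cell (col, row) has centroid
    (origin_lon + (col+0.5)*cell, origin_lat + (row+0.5)*cell)."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    def centroid(self, col: int, row: int) -> tuple[float, float]:
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise IndexError(f"cell ({col}, {row}) outside grid")
        return (self.origin_lon + (col + 0.5) * self.cell_size,
                self.origin_lat + (row + 0.5) * self.cell_size)

    def centroids(self, cells) -> np.ndarray:
        """(k, 2) lon/lat centroids for an iterable of (col, row) cells."""
        cells = list(cells)
        return np.array([self.centroid(c, r) for c, r in cells], dtype=float)


@dataclass(frozen=True)
class RegionMask:
    """A region as the set of grid cells it covers."""

    region_id: str
    cells: frozenset = field(default_factory=frozenset)  # of (col, row)

    def __post_init__(self):
        object.__setattr__(self, "cells", frozenset(tuple(c) for c in self.cells))
        if not self.cells:
            raise ValueError(f"region {self.region_id!r} has an empty cell set")

    def validate_against(self, grid: Grid) -> None:
        for col, row in self.cells:
            if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
                raise ValueError(
                    f"region {self.region_id!r}: cell ({col}, {row}) outside grid")


def rasterize_polygon(region_id: str, geometry: dict, grid: Grid) -> RegionMask:
    """Rasterize a GeoJSON polygon by centroid-in-polygon membership."""
    if shape is None:  # pragma: no cover
        raise ImportError("shapely is required to rasterize polygons")
    poly = shape(geometry)
    cells = []
    for col in range(grid.n_cols):
        for row in range(grid.n_rows):
            lon, lat = grid.centroid(col, row)
            if poly.contains(Point(lon, lat)):
                cells.append((col, row))
    return RegionMask(region_id, frozenset(cells))


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km; arguments broadcast."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def idw_weights(station_lonlat: np.ndarray, target_lonlat: np.ndarray,
                power: float = 2.0) -> np.ndarray:
    """(k_targets, n_stations) IDW weight matrix, rows normalized to 1.

    A target coincident with a station (distance 0) puts all weight on
    that station, so the station value is reproduced exactly.
    """
    if power <= 0:
        raise ValueError("IDW power must be > 0")
    s = np.atleast_2d(np.asarray(station_lonlat, dtype=float))
    t = np.atleast_2d(np.asarray(target_lonlat, dtype=float))
    d = haversine_km(t[:, None, 0], t[:, None, 1], s[None, :, 0], s[None, :, 1])
    w = np.zeros_like(d)
    zero = d <= 1e-12
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w[~any_zero] = d[~any_zero] ** (-power)
    # coincident station(s): exact pass-through
    w[any_zero] = zero[any_zero].astype(float)
    return w / w.sum(axis=1, keepdims=True)


def idw_interpolate(obs: pd.DataFrame, targets, power: float = 2.0,
                    value_col: str = "value") -> np.ndarray:
    """Interpolate one day's station values to target points.

    Parameters
    ----------
    obs
        DataFrame with columns ``lon``, ``lat`` and ``value_col``; NaN
        values mean the station did not report and are dropped.
    targets
        (k, 2) array-like of lon/lat target points.

    Returns the interpolated value at each target:
    ``sum_i w_i v_i / sum_i w_i`` with ``w_i = d_i^(-power)``.
    """
    obs = obs.dropna(subset=[value_col])
    if len(obs) == 0:
        raise MissingDataError("no station reports a value for this day")
    w = idw_weights(obs[["lon", "lat"]].to_numpy(), np.atleast_2d(targets), power)
    return w @ obs[value_col].to_numpy(dtype=float)


def zonal_mean(cell_values: dict | pd.Series, mask: RegionMask) -> float:
    """Unweighted arithmetic mean of the masked cells' values."""
    vals = []
    for cell in mask.cells:
        if cell not in cell_values:
            raise KeyError(f"no value for cell {cell} in region {mask.region_id!r}")
        vals.append(cell_values[cell])
    return float(np.mean(vals))


def _check_contiguous(dates: pd.DatetimeIndex) -> None:
    expected = pd.date_range(dates.min(), dates.max(), freq="D")
    missing = expected.difference(dates)
    if len(missing):
        shown = ", ".join(str(d.date()) for d in missing[:5])
        raise MissingDataError(
            f"date gap: {len(missing)} missing day(s), starting {shown}")


def build_region_series(stations: pd.DataFrame, grid: Grid, masks, dates=None,
                        power: float = 2.0) -> pd.DataFrame:
    """Daily regional weather via IDW-to-grid then zonal mean.

    Parameters
    ----------
    stations
        Long-format station observations with columns ``station``, ``lon``,
        ``lat``, ``date`` and the weather variables ``tmean``, ``tmax``,
        ``tmin``, ``rh``.
    masks
        Iterable of :class:`RegionMask`; only the masked cells are
        interpolated, never the full grid.
    dates
        Optional subset of dates (default: every date in ``stations``);
        must be contiguous daily.

    Returns a DataFrame with columns region_id, date, tmean, tmax, tmin, rh,
    sorted by region then date.
    """
    masks = list(masks)
    for m in masks:
        m.validate_against(grid)
    st = stations.copy()
    st["date"] = pd.to_datetime(st["date"])
    if dates is None:
        dates = pd.DatetimeIndex(sorted(st["date"].unique()))
    else:
        dates = pd.DatetimeIndex(pd.to_datetime(dates))
    _check_contiguous(dates)

    # one centroid list covering all masked cells; stations are static, so
    # the weight matrix is computed once per (full-reporting) day pattern
    all_cells = sorted({c for m in masks for c in m.cells})
    cell_pos = {c: i for i, c in enumerate(all_cells)}
    targets = grid.centroids(all_cells)

    coords = st.groupby("station")[["lon", "lat"]].first()
    full_w = idw_weights(coords.to_numpy(), targets, power)
    station_order = list(coords.index)

    missing_obs = dates.difference(pd.DatetimeIndex(st["date"].unique()))
    if len(missing_obs):
        raise MissingDataError(
            f"no station observations on {missing_obs[0].date()} "
            f"({len(missing_obs)} day(s) missing)")
    wanted = set(dates)
    rows = []
    for day, day_obs in st.set_index("date").groupby(level=0):
        if day not in wanted:
            continue
        day_obs = day_obs.set_index("station").reindex(station_order)
        rec: dict[str, dict] = {}
        for var in WEATHER_VARS:
            v = day_obs[var].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            if not ok.any():
                raise MissingDataError(
                    f"all stations missing {var!r} on {day.date()}")
            if ok.all():
                interp = full_w @ v
            else:
                w = idw_weights(coords.to_numpy()[ok], targets, power)
                interp = w @ v[ok]
            rec[var] = interp
        for m in masks:
            idx = [cell_pos[c] for c in m.cells]
            rows.append({
                "region_id": m.region_id, "date": day,
                **{var: float(np.mean(rec[var][idx])) for var in WEATHER_VARS},
            })
    out = pd.DataFrame(rows).sort_values(["region_id", "date"]).reset_index(drop=True)
    # interpolation cannot leave the convex hull of values, but clip rh to
    # its physical range against floating-point wobble
    out["rh"] = out["rh"].clip(0.0, 100.0)
    return out
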