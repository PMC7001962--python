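"""Ensemble summarisation, inverse-distance-weighted mapping and output writers.

Per-site results from the climate-model ensemble are reduced to order
statistics (median, quartiles, extremes; linear interpolation convention).
Site values are spread to a regular latitude/longitude grid with inverse
distance weighting (power 2 by default, all stations, exact at station
locations), with distances measured on a local equirectangular projection --
adequate at the extent of a single country.  Grids are written in the Esri
ASCII raster dialect; tabular results go to CSV and summaries to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleSummary",
    "MapGrid",
    "ensemble_summary",
    "idw_interpolate",
    "write_esri_ascii",
    "write_summary_json",
    "read_summary_json",
]

#: Kilometres per degree of latitude (spherical earth).
KM_PER_DEG = 111.195


@dataclass(frozen=True)
class EnsembleSummary:
    """Order statistics of one quantity across ensemble members."""

    median: float
    minimum: float
    maximum: float
    q25: float
    q75: float
    n_members: int
    members: tuple = field(default=(), repr=False)

    def __post_init__(self):
        if not (self.minimum <= self.q25 <= self.median
                <= self.q75 <= self.maximum):
            raise ValueError("order statistics out of order")


def ensemble_summary(member_values) -> EnsembleSummary:
    """Median, quartiles and range across ensemble members (>= 1 required)."""
    vals = np.asarray(list(member_values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one ensemble member")
    return EnsembleSummary(
        median=float(np.median(vals)),
        minimum=float(np.min(vals)),
        maximum=float(np.max(vals)),
        q25=float(np.percentile(vals, 25)),
        q75=float(np.percentile(vals, 75)),
        n_members=int(vals.size),
        members=tuple(float(v) for v in vals),
    )


@dataclass
class MapGrid:
    """A regular lat/lon grid of interpolated values.

    ``values[0, 0]`` is the north-west corner (row-major, as rendered in the
    Esri ASCII dialect); ``lat``/``lon`` give cell-centre coordinates.
    """

    lat: np.ndarray       # (nrows,), descending
    lon: np.ndarray       # (ncols,), ascending
    values: np.ndarray    # (nrows, ncols)
    power: float
    cellsize: float       # degrees
    station_lat: np.ndarray = None
    station_lon: np.ndarray = None


def idw_interpolate(
    station_lat,
    station_lon,
    station_values,
    lat_min: float,
    lat_max: float,
    lon_min: float,
    lon_max: float,
    cellsize: float = 0.25,
    power: float = 2.0,
) -> MapGrid:
    """Inverse-distance-weighted interpolation of station values to a grid.

    Cell value = sum(w_i v_i) / sum(w_i) with w_i = d_i^-power over all
    stations; a cell whose centre coincides with a station takes that
    station's value exactly.  Distances are equirectangular kilometres.
    Duplicate station coordinates carrying different values are an error.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    slat = np.asarray(station_lat, dtype=float)
    slon = np.asarray(station_lon, dtype=float)
    svals = np.asarray(station_values, dtype=float)
    if not (len(slat) == len(slon) == len(svals)) or len(slat) == 0:
        raise ValueError("need >= 1 station with matching coordinate/value arrays")

    # Duplicate-coordinate check.
    for i in range(len(slat)):
        same = (np.abs(slat - slat[i]) < 1e-9) & (np.abs(slon - slon[i]) < 1e-9)
        if np.any(same & (np.abs(svals - svals[i]) > 1e-12)):
            raise ValueError(
                f"duplicate station coordinates ({slat[i]}, {slon[i]}) "
                "with conflicting values"
            )

    lats = np.arange(lat_max, lat_min - 1e-9, -cellsize)
    lons = np.arange(lon_min, lon_max + 1e-9, cellsize)
    mean_lat = np.deg2rad((lat_min + lat_max) / 2.0)
    coslat = np.cos(mean_lat)

    glat = lats[:, None, None]
    glon = lons[None, :, None]
    dy = (glat - slat[None, None, :]) * KM_PER_DEG
    dx = (glon - slon[None, None, :]) * KM_PER_DEG * coslat
    dist = np.sqrt(dx * dx + dy * dy)

    # Clamp distances away from zero; coincident cells are patched exactly
    # below, so the clamp never leaks into the output.
    w = np.maximum(dist, 1e-12) ** (-power)
    values = (w * svals[None, None, :]).sum(axis=2) / w.sum(axis=2)
    # Exactness at (numerically) coincident cells.
    hit = dist < 1e-9
    if np.any(hit):
        rows, cols, stations = np.where(hit)
        values[rows, cols] = svals[stations]

    return MapGrid(lat=lats, lon=lons, values=values, power=power,
                   cellsize=cellsize, station_lat=slat, station_lon=slon)


def write_esri_ascii(grid: MapGrid, path, nodata: float = -9999.0) -> None:
    """Write a map grid as an Esri ASCII raster (cell-centre registration)."""
    nrows, ncols = grid.values.shape
    xll = float(grid.lon[0] - grid.cellsize / 2.0)
    yll = float(grid.lat[-1] - grid.cellsize / 2.0)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {grid.cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        vals = np.where(np.isfinite(grid.values), grid.values, nodata)
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _jsonable(obj):
    if isinstance(obj, EnsembleSummary):
        return {k: _jsonable(v) for k, v in obj.__dict__.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.tolist()
    return obj


def write_summary_json(summary: dict, path) -> None:
    """Round-trippable JSON dump of a (possibly nested) summary mapping."""
    with open(path, "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
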