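"""Plain-text readers and writers for the pipeline's artifacts.

Rasters use the ESRI ASCII grid format (``.asc``): a 6-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
row-major values, northernmost row first — readable by any GIS.
Protected-area polygons go to GeoJSON; occurrence tables to CSV with the
header ``species,lon,lat,year,source``.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .grid import GridSpec
from .occurrences import REQUIRED_COLUMNS

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_geojson",
    "read_geojson",
    "write_occurrences",
    "read_occurrences",
]

NODATA = -9999.0


def write_ascii_grid(path, values: np.ndarray, grid: GridSpec) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    west, south, _, _ = grid.bounds
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {west}\n"
        f"yllcorner {south}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
    )
    return values, grid


def write_geojson(path, polygons: list[Polygon]) -> None:
    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)}
        for i, p in enumerate(polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> list[Polygon]:
    with open(path) as fh:
        data = json.load(fh)
    return [shape(f["geometry"]) for f in data["features"]]


def write_occurrences(path, occ: pd.DataFrame) -> None:
    occ.loc[:, REQUIRED_COLUMNS].to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: occurrence CSV lacks columns {missing}")
    return df
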