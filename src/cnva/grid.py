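"""Regular geographic grids.

Every raster in this package lives on a plain longitude/latitude (WGS84)
grid described by :class:`GridSpec`.  Row 0 is the northernmost row and
column 0 the westernmost column, matching the storage convention of most
raster formats; cells are square in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GridSpec"]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.
    cell_size
        Cell edge length in degrees (cells are square in degrees).
    origin_lon
        Longitude of the west edge of the grid.
    origin_lat
        Latitude of the *north* edge of the grid (rows run southwards).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float = 73.0
    origin_lat: float = 40.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- extent ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) in degrees."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    # -- cell centers ----------------------------------------------------

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(LON, LAT) arrays of cell-center coordinates, shape (n_rows, n_cols)."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    # -- point location --------------------------------------------------

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing the given points.

        Points outside the grid get clipped indices; use :meth:`contains`
        to filter them first when that matters.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        return (
            np.clip(row, 0, self.n_rows - 1),
            np.clip(col, 0, self.n_cols - 1),
        )

    def contains(self, lon, lat) -> np.ndarray:
        west, south, east, north = self.bounds
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= west) & (lon < east) & (lat > south) & (lat <= north)

    # -- cropping --------------------------------------------------------

    def crop(self, bounds: tuple[float, float, float, float]):
        """Clip to ``(west, south, east, north)``.

        Returns ``(sub_grid, row_slice, col_slice)``; raises ``ValueError``
        on an empty intersection.
        """
        west, south, east, north = bounds
        gw, gs, ge, gn = self.bounds
        w, e = max(west, gw), min(east, ge)
        s, n = max(south, gs), min(north, gn)
        if not (w < e and s < n):
            raise ValueError(f"bounds {bounds} do not intersect grid extent {self.bounds}")
        c0 = int(np.floor((w - gw) / self.cell_size + 1e-9))
        c1 = int(np.ceil((e - gw) / self.cell_size - 1e-9))
        r0 = int(np.floor((gn - n) / self.cell_size + 1e-9))
        r1 = int(np.ceil((gn - s) / self.cell_size - 1e-9))
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"bounds {bounds} select an empty cell range")
        sub = replace(
            self,
            n_rows=r1 - r0,
            n_cols=c1 - c0,
            origin_lon=gw + c0 * self.cell_size,
            origin_lat=gn - r0 * self.cell_size,
        )
        return sub, slice(r0, r1), slice(c0, c1)

    def cell_area_weights(self) -> np.ndarray:
        """cos(latitude) area weights per row, broadcast to the grid shape."""
        w = np.cos(np.deg2rad(self.lat_centers()))
        return np.repeat(w[:, None], self.n_cols, axis=1)
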