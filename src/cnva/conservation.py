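"""Protected-area coverage and human-footprint coupling.

Protected-area polygons are rasterized by the cell-center-in-polygon
rule (deterministic, and exact for edge-snapped rectangles).  Coverage
is reported as a percentage of range cells, optionally cos-latitude
area-weighted, and broken down by vulnerability class so that the
per-class protected shares sum to the total coverage by construction.

The human footprint is resampled bilinearly to the analysis grid,
min-max normalized over range cells, and coupled additively:
``c(x) = min(1, v(x) + alpha * hf(x))``.  Coupling never decreases a
cell's vulnerability for alpha >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

from .grid import GridSpec
from .ranges import RangeEstimate
from .surfaces import CLASS_NAMES, ClassifiedSurface

__all__ = [
    "ConservationSummary",
    "rasterize_polygons",
    "pa_coverage",
    "coverage_by_class",
    "resample_to_grid",
    "couple_footprint",
]


@dataclass
class ConservationSummary:
    species: str
    scenario: str
    range_cells: int
    pa_coverage_pct: float
    class_area_pct: dict[str, float]  # % of range per vulnerability class
    class_pa_pct: dict[str, float]  # PA-covered % of range, per class
    footprint_mean_by_class: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "species": self.species,
            "scenario": self.scenario,
            "range_cells": self.range_cells,
            "pa_total": self.pa_coverage_pct,
        }
        for name in CLASS_NAMES:
            row[name] = self.class_area_pct[name]
            row[f"{name}_pa"] = self.class_pa_pct[name]
            if self.footprint_mean_by_class:
                row[f"{name}_footprint"] = self.footprint_mean_by_class[name]
        return row


def rasterize_polygons(polygons: list[Polygon], grid: GridSpec) -> np.ndarray:
    """Boolean raster: True where the cell center falls inside the union."""
    if not polygons:
        return np.zeros(grid.shape, dtype=bool)
    union = shapely.union_all([shapely.make_valid(p) for p in polygons])
    lon, lat = grid.center_mesh()
    return shapely.contains_xy(union, lon.ravel(), lat.ravel()).reshape(grid.shape)


def _weights(grid: GridSpec, weighting: str) -> np.ndarray:
    if weighting == "cells":
        return np.ones(grid.shape)
    if weighting == "area":
        return grid.cell_area_weights()
    raise ValueError(f"unknown weighting {weighting!r} (use 'cells' or 'area')")


def pa_coverage(
    range_est: RangeEstimate,
    polygons: list[Polygon],
    weighting: str = "cells",
) -> float:
    """Percent of the range covered by the protected-area union."""
    w = _weights(range_est.grid, weighting)
    pa = rasterize_polygons(polygons, range_est.grid)
    total = float(w[range_est.in_range].sum())
    if total == 0:
        raise ValueError("empty range")
    return 100.0 * float(w[range_est.in_range & pa].sum()) / total


def coverage_by_class(
    classified: ClassifiedSurface,
    polygons: list[Polygon],
    weighting: str = "cells",
    footprint: np.ndarray | None = None,
) -> ConservationSummary:
    """Area and protected shares of the range per vulnerability class.

    All percentages are relative to the whole range, so the class area
    shares sum to 100 and the per-class protected shares sum to the
    total protected coverage.
    """
    grid = classified.grid
    w = _weights(grid, weighting)
    pa = rasterize_polygons(polygons, grid)
    in_range = classified.in_range
    total = float(w[in_range].sum())
    if total == 0:
        raise ValueError("empty range")
    area_pct, pa_pct, fp_mean = {}, {}, {}
    for k, name in enumerate(CLASS_NAMES):
        cls = in_range & (classified.classes == k)
        area_pct[name] = 100.0 * float(w[cls].sum()) / total
        pa_pct[name] = 100.0 * float(w[cls & pa].sum()) / total
        if footprint is not None:
            fp_mean[name] = float(footprint[cls].mean()) if cls.any() else np.nan
    return ConservationSummary(
        species=classified.species,
        scenario=classified.scenario,
        range_cells=int(in_range.sum()),
        pa_coverage_pct=100.0 * float(w[in_range & pa].sum()) / total,
        class_area_pct=area_pct,
        class_pa_pct=pa_pct,
        footprint_mean_by_class=fp_mean,
    )


def resample_to_grid(
    values: np.ndarray, source: GridSpec, target: GridSpec
) -> np.ndarray:
    """Bilinear resampling of a raster between lon/lat grids."""
    if source == target:
        return values.astype(float, copy=True)
    lon, lat = target.center_mesh()
    col = (lon - source.origin_lon) / source.cell_size - 0.5
    row = (source.origin_lat - lat) / source.cell_size - 0.5
    return map_coordinates(
        values.astype(float), [row, col], order=1, mode="nearest"
    )


def couple_footprint(
    vuln: ClassifiedSurface,
    footprint: np.ndarray,
    footprint_grid: GridSpec | None = None,
    alpha: float = 0.5,
) -> tuple[ClassifiedSurface, np.ndarray | None]:
    """Couple human-footprint pressure into a vulnerability surface.

    The footprint is resampled to the analysis grid, min-max normalized
    over range cells, and added with weight ``alpha``, capped at 1:
    ``c(x) = min(1, v(x) + alpha * hf(x))``.  Returns the coupled
    surface, and the normalized footprint used.  An all-constant
    footprint cannot be normalized; coupling is skipped with a warning
    and the surface is returned unchanged.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    grid = vuln.grid
    hf = resample_to_grid(footprint, footprint_grid or grid, grid)
    vals = hf[vuln.in_range]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        warnings.warn(
            "footprint is constant over the range; coupling skipped", stacklevel=2
        )
        return vuln, None
    hf_norm = np.full(grid.shape, np.nan)
    hf_norm[vuln.in_range] = (vals - lo) / (hi - lo)
    coupled_vals = np.minimum(1.0, vuln.values + alpha * hf_norm)
    from .surfaces import classify

    coupled = ClassifiedSurface(
        grid=grid,
        in_range=vuln.in_range,
        values=coupled_vals,
        classes=classify(coupled_vals, vuln.in_range, vuln.breaks),
        breaks=vuln.breaks,
        quantity="coupled_vulnerability",
        species=vuln.species,
        scenario=vuln.scenario,
    )
    return coupled, hf_norm
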