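"""Synthetic worlds with known niche ground truth.

The generators here build everything the assessment pipeline consumes —
spatially autocorrelated, cross-correlated climate fields for a current
period and one or more emission scenarios, species occurrence records
drawn from Gaussian climate niches with controllable marginality and
specialization, rectangular protected-area polygons, and a
hotspot-structured human-footprint raster — so that every downstream
stage can be exercised and validated without external data downloads.

Design notes
------------
* Spatial autocorrelation comes from Gaussian smoothing of white noise;
  ``spatial_range`` is the smoothing kernel width in cells.
* Cross-variable correlation is imposed by multiplying independent
  smoothed fields by the Cholesky factor of the target correlation
  matrix, which is exact in expectation.
* Future climate equals current climate plus a smooth shift field scaled
  so that the background mean absolute shift per variable, in units of
  that variable's background SD, equals the scenario's
  ``shift_amplitude`` exactly.  A configurable fraction of the shift is
  carried by a west-to-east gradient so that spatially structured
  exposure patterns are recoverable.
* Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

from .grid import GridSpec
from .stack import ClimateStack

__all__ = [
    "WorldSpec",
    "SpeciesSpec",
    "generate_climate",
    "generate_species",
    "generate_protected_areas",
    "generate_footprint",
]

# Default scenario amplitudes: the moderate and high emission pathways
# used throughout the package, with the high pathway shifting twice as far.
DEFAULT_SHIFTS = {"SSP2-4.5": 0.3, "SSP5-8.5": 0.6}


def _default_correlation(p: int) -> np.ndarray:
    """AR(1)-style correlation 0.3^|i-j|: mild, positive-definite."""
    idx = np.arange(p)
    return 0.3 ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class WorldSpec:
    """Specification of a synthetic study region and its climate.

    ``shift_amplitude`` maps scenario label to the mean absolute
    future-minus-current change per variable, in background-SD units.
    ``shift_gradient`` in [0, 1] is the fraction of shift-field variance
    carried by a deterministic west-high/east-low gradient.
    """

    n_rows: int = 64
    n_cols: int = 64
    cell_size: float = 0.25
    origin_lon: float = 73.0
    origin_lat: float = 40.0
    n_vars: int = 6
    var_correlation: np.ndarray | None = None
    spatial_range: float = 5.0
    shift_amplitude: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHIFTS)
    )
    shift_gradient: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.var_correlation is None:
            self.var_correlation = _default_correlation(self.n_vars)
        self.var_correlation = np.asarray(self.var_correlation, dtype=float)
        R = self.var_correlation
        if R.shape != (self.n_vars, self.n_vars):
            raise ValueError("var_correlation must be n_vars x n_vars")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError(f"var_correlation is not symmetric:\n{R}")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError(f"var_correlation diagonal is not 1:\n{R}")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"var_correlation is not positive definite:\n{R}"
            ) from None
        for lab, amp in self.shift_amplitude.items():
            if amp < 0:
                raise ValueError(f"shift_amplitude[{lab!r}] must be >= 0")
        if not 0.0 <= self.shift_gradient <= 1.0:
            raise ValueError("shift_gradient must lie in [0, 1]")
        if not self.spatial_range > 0:
            raise ValueError("spatial_range must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            self.n_rows, self.n_cols, self.cell_size, self.origin_lon, self.origin_lat
        )

    @property
    def variables(self) -> list[str]:
        names = ["MDR", "ISO", "MTWQ", "PS", "PWQ", "PCQ"]
        if self.n_vars <= len(names):
            return names[: self.n_vars]
        return names + [f"VAR{i}" for i in range(len(names), self.n_vars)]


@dataclass
class SpeciesSpec:
    """A Gaussian climate niche in the standardized (global-SD) frame."""

    name: str = "species"
    niche_center: np.ndarray = field(default_factory=lambda: np.zeros(6))
    niche_sd: np.ndarray = field(default_factory=lambda: np.ones(6))
    n_occurrences: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.niche_center = np.atleast_1d(np.asarray(self.niche_center, dtype=float))
        self.niche_sd = np.atleast_1d(np.asarray(self.niche_sd, dtype=float))
        if np.any(self.niche_sd <= 0):
            raise ValueError("niche_sd must be positive elementwise")
        if self.n_occurrences < 5:
            raise ValueError("n_occurrences must be at least 5")


def _smooth_unit_field(rng: np.random.Generator, shape, spatial_range: float) -> np.ndarray:
    """Smoothed white noise rescaled to mean 0, SD 1 over the grid."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=spatial_range, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_climate(
    spec: WorldSpec,
) -> tuple[ClimateStack, dict[str, ClimateStack]]:
    """Generate the current climate stack and one future stack per scenario.

    Returns ``(current, {scenario_label: future})``.  Deterministic for a
    fixed spec (the scenario order in ``shift_amplitude`` does not affect
    the fields: each scenario gets its own child seed keyed by sorted
    label position).
    """
    grid = spec.grid
    shape = grid.shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))

    raw = np.stack(
        [_smooth_unit_field(rng, shape, spec.spatial_range) for _ in range(spec.n_vars)]
    )
    # Empirically whiten the realized fields before mixing: smoothing leaves
    # residual sample correlation between them, so the Cholesky mix alone is
    # only exact in expectation.  Whitening makes the realized cross-variable
    # correlation match var_correlation exactly.
    X = raw.reshape(spec.n_vars, -1)
    W = np.linalg.cholesky(X @ X.T / X.shape[1])
    X_white = np.linalg.solve(W, X)
    L = np.linalg.cholesky(spec.var_correlation)
    current_vals = (L @ X_white).reshape(spec.n_vars, *shape)

    mask = np.ones(shape, dtype=bool)
    current = ClimateStack(
        grid=grid,
        variables=spec.variables,
        values=current_vals,
        mask=mask,
        label="current",
    )

    sigma = current_vals.reshape(spec.n_vars, -1).std(axis=1)
    # West-high gradient over columns, zero-mean, unit mean-absolute-value.
    grad_cols = np.linspace(1.0, -1.0, grid.n_cols)
    grad = np.repeat(grad_cols[None, :], grid.n_rows, axis=0)
    grad /= np.abs(grad).mean()

    futures: dict[str, ClimateStack] = {}
    for k, label in enumerate(sorted(spec.shift_amplitude)):
        amp = spec.shift_amplitude[label]
        srng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + k]))
        fut_vals = current_vals.copy()
        if amp > 0:
            for j in range(spec.n_vars):
                noise = _smooth_unit_field(srng, shape, spec.spatial_range)
                f = (1 - spec.shift_gradient) * noise + spec.shift_gradient * grad
                # scale so background mean |shift| / sigma_j == amp exactly
                f = f / np.abs(f).mean()
                fut_vals[j] = current_vals[j] + amp * sigma[j] * f
        futures[label] = ClimateStack(
            grid=grid,
            variables=spec.variables,
            values=fut_vals,
            mask=mask,
            label=label,
        )
    return current, futures


class EmptyNicheError(ValueError):
    """The requested niche has no appreciable density anywhere on the grid."""


def generate_species(spec: SpeciesSpec, climate: ClimateStack) -> pd.DataFrame:
    """Sample occurrence records from a Gaussian niche over the climate grid.

    Cells are drawn without replacement with probability proportional to
    the Gaussian niche density evaluated at each background cell's
    standardized climate; one record per sampled cell, with coordinates
    jittered uniformly within the cell.
    """
    if len(spec.niche_center) != climate.n_vars:
        raise ValueError(
            f"niche has {len(spec.niche_center)} dimensions but climate has "
            f"{climate.n_vars} variables"
        )
    rng = np.random.default_rng(spec.seed)
    Z = climate.background_matrix()  # (N, P) raw values
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    zs = (Z - mu) / sd

    dev = (zs - spec.niche_center) / spec.niche_sd
    log_density = -0.5 * np.sum(dev**2, axis=1)
    density = np.exp(log_density - log_density.max())
    # absolute (unshifted) density check for the empty-niche failure mode
    if np.exp(log_density.max()) <= 1e-12:
        raise EmptyNicheError(
            f"niche of {spec.name!r} has density <= 1e-12 at every background cell"
        )
    p = density / density.sum()
    n_avail = int((p > 0).sum())
    if spec.n_occurrences > n_avail:
        raise EmptyNicheError(
            f"niche of {spec.name!r} supports only {n_avail} cells; "
            f"cannot draw {spec.n_occurrences} distinct occurrences"
        )
    chosen = rng.choice(len(p), size=spec.n_occurrences, replace=False, p=p)

    rows, cols = np.nonzero(climate.mask)
    grid = climate.grid
    lon = grid.origin_lon + (cols[chosen] + rng.uniform(0.05, 0.95, len(chosen))) * grid.cell_size
    lat = grid.origin_lat - (rows[chosen] + rng.uniform(0.05, 0.95, len(chosen))) * grid.cell_size
    years = rng.integers(1960, 2021, size=len(chosen))
    return pd.DataFrame(
        {
            "species": spec.name,
            "lon": lon,
            "lat": lat,
            "year": years,
            "source": "synthetic",
        }
    )


def generate_protected_areas(
    grid: GridSpec,
    coverage_fraction: float,
    n_polygons: int = 8,
    seed: int = 0,
    mask: np.ndarray | None = None,
    tolerance: float = 0.02,
) -> list[Polygon]:
    """Axis-aligned rectangular protected areas covering a target fraction.

    Rectangles snap to cell edges so that cell-center rasterization is
    exact.  The union covers ``coverage_fraction`` of the background
    cells to within ``tolerance`` (fraction of all background cells);
    if that cannot be achieved with ``n_polygons`` rectangles a
    ``ValueError`` reports the shortfall.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must lie in [0, 1]")
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    n_bg = int(mask.sum())
    target = coverage_fraction * n_bg
    if target < 0.5:
        return []

    rng = np.random.default_rng(seed)
    covered = np.zeros(grid.shape, dtype=bool)
    polys: list[Polygon] = []
    for i in range(n_polygons):
        remaining = target - int((covered & mask).sum())
        if remaining < 0.5:
            break
        want = remaining / (n_polygons - i)
        side = max(1, int(round(np.sqrt(want))))
        h = min(grid.n_rows, max(1, int(round(side * rng.uniform(0.6, 1.6)))))
        w = min(grid.n_cols, max(1, int(round(want / h))))
        # try several placements, keep the one whose new coverage is closest
        # to what this rectangle should contribute
        best = None
        for _ in range(50):
            r0 = int(rng.integers(0, grid.n_rows - h + 1))
            c0 = int(rng.integers(0, grid.n_cols - w + 1))
            new = int((mask[r0 : r0 + h, c0 : c0 + w] & ~covered[r0 : r0 + h, c0 : c0 + w]).sum())
            score = abs(new - min(want, remaining))
            if best is None or score < best[0]:
                best = (score, r0, c0)
        _, r0, c0 = best
        covered[r0 : r0 + h, c0 : c0 + w] = True
        west = grid.origin_lon + c0 * grid.cell_size
        east = grid.origin_lon + (c0 + w) * grid.cell_size
        north = grid.origin_lat - r0 * grid.cell_size
        south = grid.origin_lat - (r0 + h) * grid.cell_size
        polys.append(box(west, south, east, north))

    achieved = int((covered & mask).sum())
    if abs(achieved - target) / n_bg > tolerance:
        raise ValueError(
            f"coverage_fraction {coverage_fraction} infeasible with "
            f"{n_polygons} polygons: achieved {achieved / n_bg:.3f}"
        )
    return polys


def generate_footprint(
    grid: GridSpec,
    n_hotspots: int,
    seed: int = 0,
    hotspot_sd_cells: float = 4.0,
) -> np.ndarray:
    """Human-footprint raster as a sum of Gaussian bumps at random hotspots.

    Nonnegative everywhere; with a single hotspot the unique global
    maximum sits at its center cell.
    """
    if n_hotspots < 0:
        raise ValueError("n_hotspots must be >= 0")
    rng = np.random.default_rng(seed)
    fp = np.zeros(grid.shape)
    rr, cc = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    for _ in range(n_hotspots):
        r = int(rng.integers(0, grid.n_rows))
        c = int(rng.integers(0, grid.n_cols))
        amp = rng.uniform(0.5, 1.5)
        fp += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * hotspot_sd_cells**2))
    return fp
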