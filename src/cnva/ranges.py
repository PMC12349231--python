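"""Range estimation by inverse distance weighting and habitat weights.

A species' distribution range is delineated by interpolating presence
points (value 1) against pseudo-absence points (value 0) with inverse
distance weighting (IDW) over the background grid, then thresholding the
resulting [0, 1] score surface.  Pseudo-absences are sampled uniformly
over the background excluding a buffer around the presences, with a
fixed seed; the IDW exponent and the threshold are conventional choices
(power 2, threshold 0.5).  Distances are great-circle km, not degrees,
to avoid latitude distortion.

Habitat-utilization weights :math:`p_i` over the range cells (summing to
1) can be uniform, proportional to the IDW score, or placed on the
occurrence cells alone (the occurrences-as-range robustness mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec
from .occurrences import haversine_km

__all__ = [
    "RangeEstimate",
    "HabitatWeights",
    "idw_score",
    "estimate_range_idw",
    "habitat_weights",
    "occurrence_weights",
]


@dataclass
class RangeEstimate:
    grid: GridSpec
    in_range: np.ndarray  # bool raster, subset of background
    score: np.ndarray  # IDW score in [0,1], NaN outside background
    threshold: float

    @property
    def n_cells(self) -> int:
        return int(self.in_range.sum())


@dataclass
class HabitatWeights:
    """Per-cell habitat-utilization weights p_i; zero outside the range."""

    grid: GridSpec
    weights: np.ndarray  # (n_rows, n_cols), sums to 1 over range cells

    def __post_init__(self) -> None:
        total = float(np.nansum(self.weights))
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"habitat weights must sum to 1 (got {total})")
        if np.nanmin(self.weights) < 0:
            raise ValueError("habitat weights must be nonnegative")

    @property
    def support(self) -> np.ndarray:
        return np.nan_to_num(self.weights) > 0


def idw_score(
    point_lon: np.ndarray,
    point_lat: np.ndarray,
    point_value: np.ndarray,
    query_lon: np.ndarray,
    query_lat: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """IDW interpolation of point values at query locations.

    ``score(x) = sum_k v_k d(x, x_k)^-power / sum_k d(x, x_k)^-power``;
    a query coinciding with a data point takes that point's exact value
    (first such point wins, relevant only for coincident data points).
    """
    d = haversine_km(
        np.asarray(query_lon, float)[:, None],
        np.asarray(query_lat, float)[:, None],
        np.asarray(point_lon, float)[None, :],
        np.asarray(point_lat, float)[None, :],
    )
    values = np.asarray(point_value, float)
    out = np.empty(d.shape[0])
    hit = d <= 1e-12
    any_hit = hit.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=1)
    safe = denom > 0
    out[safe] = (w[safe] @ values) / denom[safe]
    out[~safe] = np.nan
    if any_hit.any():
        first = np.argmax(hit, axis=1)
        out[any_hit] = values[first[any_hit]]
    return out


def estimate_range_idw(
    presences: pd.DataFrame,
    grid: GridSpec,
    mask: np.ndarray,
    power: float = 2.0,
    n_pseudoabs: int | None = None,
    threshold: float = 0.5,
    seed: int = 0,
    buffer_km: float = 5.0,
) -> RangeEstimate:
    """Estimate a species range from presence records by IDW.

    Pseudo-absence points (default 10x the presences) are placed at the
    centers of background cells sampled uniformly, excluding cells within
    ``buffer_km`` of any presence.  The range is ``score >= threshold``
    together with every cell containing a presence.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    lon = presences["lon"].to_numpy(float)
    lat = presences["lat"].to_numpy(float)
    inside = grid.contains(lon, lat)
    rows, cols = grid.cell_of(lon, lat)
    inside &= mask[rows, cols]
    lon, lat = lon[inside], lat[inside]
    if len(lon) < 3:
        raise ValueError(
            f"need at least 3 presence points inside the background, got {len(lon)}"
        )
    if np.ptp(lon) < 1e-12 and np.ptp(lat) < 1e-12:
        raise ValueError("all presence points are coincident")
    if n_pseudoabs is None:
        n_pseudoabs = 10 * len(lon)

    bg_rows, bg_cols = np.nonzero(mask)
    cell_lon = grid.origin_lon + (bg_cols + 0.5) * grid.cell_size
    cell_lat = grid.origin_lat - (bg_rows + 0.5) * grid.cell_size

    pa_lon = np.empty(0)
    pa_lat = np.empty(0)
    if n_pseudoabs > 0:
        dmin = np.full(len(bg_rows), np.inf)
        for plon, plat in zip(lon, lat):
            dmin = np.minimum(dmin, haversine_km(cell_lon, cell_lat, plon, plat))
        eligible = np.nonzero(dmin > buffer_km)[0]
        rng = np.random.default_rng(seed)
        take = min(n_pseudoabs, len(eligible))
        chosen = rng.choice(eligible, size=take, replace=False)
        pa_lon, pa_lat = cell_lon[chosen], cell_lat[chosen]

    pt_lon = np.concatenate([lon, pa_lon])
    pt_lat = np.concatenate([lat, pa_lat])
    pt_val = np.concatenate([np.ones(len(lon)), np.zeros(len(pa_lon))])

    score_flat = idw_score(pt_lon, pt_lat, pt_val, cell_lon, cell_lat, power=power)
    score = np.full(grid.shape, np.nan)
    score[bg_rows, bg_cols] = score_flat

    in_range = np.zeros(grid.shape, dtype=bool)
    in_range[mask] = score_flat >= threshold
    occ_rows, occ_cols = grid.cell_of(lon, lat)
    in_range[occ_rows, occ_cols] = True
    in_range &= mask
    return RangeEstimate(grid=grid, in_range=in_range, score=score, threshold=threshold)


def habitat_weights(range_est: RangeEstimate, mode: str = "uniform") -> HabitatWeights:
    """Habitat-utilization weights over range cells; ``uniform`` or ``score``."""
    n = range_est.n_cells
    if n == 0:
        raise ValueError("range is empty; cannot build habitat weights")
    w = np.zeros(range_est.grid.shape)
    if mode == "uniform":
        w[range_est.in_range] = 1.0 / n
    elif mode == "score":
        s = np.nan_to_num(range_est.score)[range_est.in_range]
        if s.sum() <= 0:
            raise ValueError("score mode requires a positive total score")
        w[range_est.in_range] = s / s.sum()
    else:
        raise ValueError(f"unknown weighting mode {mode!r}")
    return HabitatWeights(grid=range_est.grid, weights=w)


def occurrence_weights(
    occ: pd.DataFrame, grid: GridSpec, mask: np.ndarray
) -> HabitatWeights:
    """Weights proportional to occurrence counts per cell (records-as-range)."""
    lon = occ["lon"].to_numpy(float)
    lat = occ["lat"].to_numpy(float)
    inside = grid.contains(lon, lat)
    rows, cols = grid.cell_of(lon[inside], lat[inside])
    keep = mask[rows, cols]
    rows, cols = rows[keep], cols[keep]
    if len(rows) == 0:
        raise ValueError("no occurrences fall inside the background")
    w = np.zeros(grid.shape)
    np.add.at(w, (rows, cols), 1.0)
    w /= w.sum()
    return HabitatWeights(grid=grid, weights=w)
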