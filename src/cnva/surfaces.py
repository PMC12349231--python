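"""Spatial surfaces: projecting niche factors onto the grid.

Per-cell sensitivity scores weight the displacement of a cell's climate
from the species' niche centroid along each factor axis by that axis'
specialization amount; per-cell exposure is the RMS standardized climate
change.  Each surface is min-max normalized to [0, 1] over the species'
range cells and classified into low/medium/high at breaks of 1/3 and
2/3 (values exactly on a break are assigned upward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnfa import NicheModel
from .grid import GridSpec
from .ranges import RangeEstimate
from .stack import StandardizedStack

__all__ = [
    "ClassifiedSurface",
    "exposure_score",
    "CLASS_NAMES",
    "sensitivity_surface",
    "exposure_surface",
    "vulnerability_surface",
    "classify",
]

CLASS_NAMES = ("low", "medium", "high")


@dataclass
class ClassifiedSurface:
    """A [0, 1] surface over range cells with tertile classes.

    ``values`` is NaN outside the range; ``classes`` is -1 outside, else
    0 (low), 1 (medium) or 2 (high).
    """

    grid: GridSpec
    in_range: np.ndarray
    values: np.ndarray
    classes: np.ndarray
    breaks: tuple[float, float]
    quantity: str
    species: str = "species"
    scenario: str = ""
    raw_values: np.ndarray | None = None  # pre-normalization scores

    def class_shares(self) -> dict[str, float]:
        """Percent of range cells in each class (sums to 100)."""
        n = int(self.in_range.sum())
        return {
            name: 100.0 * float((self.classes[self.in_range] == k).sum()) / n
            for k, name in enumerate(CLASS_NAMES)
        }


def classify(
    values: np.ndarray,
    in_range: np.ndarray,
    breaks: tuple[float, float] = (1 / 3, 2 / 3),
) -> np.ndarray:
    """Classify a [0, 1] surface into low/medium/high tertile classes.

    Bins are left-closed: [0, b1), [b1, b2), [b2, 1]; a value exactly on
    a break is assigned to the upper class.
    """
    b1, b2 = breaks
    if not 0 < b1 < b2 < 1:
        raise ValueError("breaks must be strictly increasing within (0, 1)")
    v = values[in_range]
    if np.nanmin(v) < 0 or np.nanmax(v) > 1:
        raise ValueError("surface values outside [0, 1] cannot be classified")
    classes = np.full(values.shape, -1, dtype=np.int8)
    classes[in_range] = np.where(v < b1, 0, np.where(v < b2, 1, 2))
    return classes


def _minmax_over_range(raw: np.ndarray, in_range: np.ndarray, what: str) -> np.ndarray:
    """Min-max normalize over range cells; an all-equal nonzero surface is
    degenerate, but an identically-zero surface (no change anywhere) is
    passed through as zeros."""
    vals = raw[in_range]
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    out = np.full(raw.shape, np.nan)
    if hi == lo:
        if lo == 0.0:
            out[in_range] = 0.0
            return out
        raise ValueError(f"constant surface: {what} is {lo} at every range cell")
    out[in_range] = (vals - lo) / (hi - lo)
    return out


def _finish(
    grid, in_range, normalized, quantity, species, scenario="", breaks=(1 / 3, 2 / 3), raw=None
) -> ClassifiedSurface:
    return ClassifiedSurface(
        grid=grid,
        in_range=in_range,
        values=normalized,
        classes=classify(normalized, in_range, breaks),
        breaks=breaks,
        quantity=quantity,
        species=species,
        scenario=scenario,
        raw_values=raw,
    )


def sensitivity_surface(
    model: NicheModel, stack: StandardizedStack, range_est: RangeEstimate
) -> ClassifiedSurface:
    """Project the niche model onto the range.

    Raw per-cell score: ``sum_k rho_k |sum_j w_jk (z_j(x) - c_j)| /
    sum_k rho_k`` where ``c`` is the species niche centroid (the
    marginality vector in the standardized frame).  A cell at the
    centroid scores 0; displacement along high-specialization axes is
    weighted up.  Min-max normalized over range cells.
    """
    if model.variables != stack.variables:
        raise ValueError("model and stack variable sets differ")
    if stack.grid != range_est.grid:
        raise ValueError("stack and range are on different grids")
    in_range = range_est.in_range & stack.mask
    Z = stack.values  # (P, rows, cols)
    dev = Z - model.m[:, None, None]
    # axis scores: |w[:,k] . dev| per cell
    proj = np.einsum("jk,jrc->krc", model.w, dev)
    raw = np.einsum("k,krc->rc", model.rho, np.abs(proj)) / model.rho.sum()
    n_masked = int(np.isnan(raw[in_range]).sum())
    if n_masked:
        import logging

        logging.getLogger(__name__).warning(
            "%d range cells have masked climate; set to NaN", n_masked
        )
    return _finish(
        stack.grid,
        in_range,
        _minmax_over_range(raw, in_range, "sensitivity score"),
        "sensitivity",
        model.species,
        raw=raw,
    )


def exposure_score(
    current: StandardizedStack, future: StandardizedStack
) -> np.ndarray:
    """Raw per-cell exposure ``sqrt(sum_j (g_j - z_j)^2 / P)``."""
    if not current.same_frame(future):
        raise ValueError("current and future stacks are not in one frame")
    return np.sqrt(
        np.sum((future.values - current.values) ** 2, axis=0) / current.n_vars
    )


def exposure_surface(
    current: StandardizedStack,
    future: StandardizedStack,
    range_est: RangeEstimate,
    species: str = "species",
) -> ClassifiedSurface:
    """Per-cell RMS standardized climate change over the range.

    ``eps(x) = sqrt(sum_j (g_j - z_j)^2 / P)``; a uniform +1-SD shift in
    every variable gives raw eps = 1 everywhere.  If future equals
    current the surface is identically zero (normalization skipped).
    """
    if not current.same_frame(future):
        raise ValueError("current and future stacks are not in one frame")
    if current.grid != range_est.grid:
        raise ValueError("stacks and range are on different grids")
    in_range = range_est.in_range & current.mask
    raw = exposure_score(current, future)
    return _finish(
        current.grid,
        in_range,
        _minmax_over_range(raw, in_range, "exposure score"),
        "exposure",
        species,
        future.label,
        raw=raw,
    )


def vulnerability_surface(
    sens: ClassifiedSurface, expo: ClassifiedSurface
) -> ClassifiedSurface:
    """Cellwise combination ``v = sqrt(s' (1 + e'))``, re-normalized.

    Monotone in both inputs: raising a cell's normalized exposure never
    lowers its vulnerability value or class.
    """
    if sens.grid != expo.grid or not np.array_equal(sens.in_range, expo.in_range):
        raise ValueError("sensitivity and exposure surfaces do not share a grid/range")
    raw = np.sqrt(sens.values * (1.0 + expo.values))
    return _finish(
        sens.grid,
        sens.in_range,
        _minmax_over_range(raw, sens.in_range, "vulnerability score"),
        "vulnerability",
        sens.species,
        expo.scenario,
        raw=raw,
    )
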