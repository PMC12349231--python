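"""Climate exposure: departure of a range's future climate from current.

The per-variable departure factor is the habitat-weighted mean absolute
change ``d_j = sum_i p_i |g_ij - z_ij|``, with both stacks expressed in
the current-climate standardized frame so that departures are in
global-SD units.  The total exposure is the Euclidean norm
``D = sqrt(sum_j d_j^2)``.  Absolute (not signed) differences are used:
exposure measures the amount of change experienced, and signed averaging
would let opposite shifts cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ranges import HabitatWeights
from .stack import StandardizedStack

__all__ = ["DepartureResult", "departure", "total_exposure", "FrameMismatchError"]


class FrameMismatchError(ValueError):
    """Current and future stacks are not in one standardization frame."""


@dataclass
class DepartureResult:
    species: str
    scenario: str
    variables: list[str]
    d: np.ndarray  # per-variable departure factors, length P

    @property
    def D(self) -> float:
        return total_exposure(self.d)


def departure(
    current: StandardizedStack,
    future: StandardizedStack,
    weights: HabitatWeights,
    species: str = "species",
) -> DepartureResult:
    """Habitat-weighted mean absolute standardized change per variable."""
    if not current.same_frame(future):
        raise FrameMismatchError(
            "current and future stacks differ in grid, variables or "
            "standardization frame (mu/sigma)"
        )
    if current.grid != weights.grid:
        raise ValueError("habitat weights are not on the stacks' grid")
    p = np.nan_to_num(weights.weights)
    diff = np.abs(future.values - current.values)
    # weights are zero off-range, so masked NaNs outside never contribute
    d = np.nansum(diff * p[None, :, :], axis=(1, 2))
    return DepartureResult(
        species=species,
        scenario=future.label,
        variables=list(current.variables),
        d=d,
    )


def total_exposure(d: np.ndarray) -> float:
    """Total exposure ``D = sqrt(sum d_j^2)`` (Euclidean norm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("departure factors must be nonnegative")
    return float(np.linalg.norm(d))
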