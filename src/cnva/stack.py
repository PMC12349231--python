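"""Multi-variable climate raster stacks.

A :class:`ClimateStack` holds one co-registered raster per bioclimatic
variable plus a boolean background (study-area) mask.  Cells outside the
background carry NaN, never silent zeros.  A :class:`StandardizedStack`
additionally records the per-variable background mean and standard
deviation used to scale it, so that current and future stacks can share
one standardization frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = ["ClimateStack", "StandardizedStack"]


@dataclass
class ClimateStack:
    grid: GridSpec
    variables: list[str]
    values: np.ndarray  # (P, n_rows, n_cols), NaN outside background
    mask: np.ndarray  # bool (n_rows, n_cols), True = background cell
    label: str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.variables), *self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.variables)} variables on grid {self.grid.shape}"
            )
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.n_background < self.n_vars:
            raise ValueError("background must have at least as many cells as variables")

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def n_background(self) -> int:
        return int(self.mask.sum())

    def background_matrix(self) -> np.ndarray:
        """Background cell values as an (N, P) matrix (row-major cell order)."""
        return self.values[:, self.mask].T

    def select(self, variables: list[str]) -> "ClimateStack":
        idx = [self.variables.index(v) for v in variables]
        return self.__class__._rebuild(
            self, variables=list(variables), values=self.values[idx]
        )

    def same_grid(self, other: "ClimateStack") -> bool:
        return self.grid == other.grid and np.array_equal(self.mask, other.mask)

    @classmethod
    def _rebuild(cls, template: "ClimateStack", **overrides) -> "ClimateStack":
        kw = dict(
            grid=template.grid,
            variables=template.variables,
            values=template.values,
            mask=template.mask,
            label=template.label,
        )
        kw.update(overrides)
        return ClimateStack(**kw)


@dataclass
class StandardizedStack(ClimateStack):
    """A climate stack scaled to its standardization frame.

    ``mu`` and ``sigma`` are the per-variable background mean and SD of
    the *reference* (current-climate) stack; standardized values are
    ``(raw - mu) / sigma``, so the reference stack itself has background
    mean 0 and SD 1 in every variable.
    """

    mu: np.ndarray = field(default=None)  # type: ignore[assignment]
    sigma: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mu is None or self.sigma is None:
            raise ValueError("StandardizedStack requires mu and sigma")
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (self.n_vars,) or self.sigma.shape != (self.n_vars,):
            raise ValueError("mu/sigma must have one entry per variable")

    def same_frame(self, other: "StandardizedStack", atol: float = 1e-10) -> bool:
        return (
            self.same_grid(other)
            and self.variables == other.variables
            and np.allclose(self.mu, other.mu, atol=atol)
            and np.allclose(self.sigma, other.sigma, atol=atol)
        )

    def select(self, variables: list[str]) -> "StandardizedStack":
        idx = [self.variables.index(v) for v in variables]
        return StandardizedStack(
            grid=self.grid,
            variables=list(variables),
            values=self.values[idx],
            mask=self.mask,
            label=self.label,
            mu=self.mu[idx],
            sigma=self.sigma[idx],
        )
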