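"""Climate niche factor analysis (CNFA).

The factor model compares the climate occupied by a species with the
climate available across the study background, in the standardized
global frame.  Two aspects of the niche are separated:

* **marginality** — the displacement ``m`` of the species' niche
  centroid from the background centroid, in background-SD units, with
  total marginality ``M = ||m||``;
* **specialization** — the ratio of background climate variance to
  species-occupied variance along each factor axis.  Axis 1 is the
  marginality axis ``m/||m||``; the remaining axes maximize the
  generalized Rayleigh quotient ``(a' C_G a) / (a' C_S a)`` restricted to
  the subspace C_S-orthogonal to the marginality axis, where ``C_G`` and
  ``C_S`` are the background and species (habitat-weighted) covariance
  matrices.  The amounts of specialization ``rho_k`` are the variance
  ratios on the axes; large ``rho`` means a narrow niche.

Per-variable sensitivity factors are the loading-weighted sums of the
specialization amounts, ``s_i = sum_k |w_ik| rho_k`` with unit-norm
factor columns, and the total sensitivity is the square root of their
mean.  A species confined to a narrow sliver of the available climate
therefore scores high in exactly the variables that define that sliver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, eigh, solve_triangular

from .ranges import HabitatWeights
from .stack import StandardizedStack

__all__ = ["NicheModel", "fit_cnfa", "total_marginality", "total_sensitivity"]

logger = logging.getLogger(__name__)


@dataclass
class NicheModel:
    """Fitted CNFA factor model for one species."""

    species: str
    variables: list[str]
    m: np.ndarray  # marginality vector, length P (global-SD units)
    w: np.ndarray  # |loadings|, P x P, unit-norm columns; col 0 = marginality axis
    rho: np.ndarray  # specialization amounts, length P (rho[0] = marginality axis)
    s: np.ndarray  # per-variable sensitivity factors, length P
    M: float  # total marginality ||m||
    S: float  # total sensitivity sqrt(mean s)
    loadings: np.ndarray = field(repr=False, default=None)  # signed axes

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "variables": list(self.variables),
            "m": self.m.tolist(),
            "w": self.w.tolist(),
            "rho": self.rho.tolist(),
            "s": self.s.tolist(),
            "M": self.M,
            "S": self.S,
        }


def _weighted_cov(Z: np.ndarray, p: np.ndarray, mean: np.ndarray) -> np.ndarray:
    Zc = Z - mean
    return (Zc * p[:, None]).T @ Zc


def fit_cnfa(
    stack: StandardizedStack,
    weights: HabitatWeights,
    species: str = "species",
    ridge_scale: float = 1e-6,
) -> NicheModel:
    """Fit the niche factor model for one species.

    Parameters
    ----------
    stack
        Current climate in the standardized global frame (background mean
        0, SD 1 per variable).
    weights
        Habitat-utilization weights ``p_i`` over the species range
        (nonnegative, summing to 1, zero outside the range).
    ridge_scale
        If the species covariance is not positive definite, a ridge of
        ``ridge_scale * trace / P`` is added (and logged).
    """
    if stack.grid != weights.grid:
        raise ValueError("habitat weights are not on the stack's grid")
    P = stack.n_vars
    Z = stack.background_matrix()  # (N, P)
    p = np.nan_to_num(weights.weights)[stack.mask]
    if p.sum() <= 0:
        raise ValueError("habitat weights vanish on the background")
    if int((p > 0).sum()) <= P:
        raise ValueError(
            f"species occupies {(p > 0).sum()} cells; need more than P={P}"
        )
    p = p / p.sum()

    m = p @ Z
    C_S = _weighted_cov(Z, p, m)
    C_G = _weighted_cov(Z, np.full(len(Z), 1.0 / len(Z)), Z.mean(axis=0))

    try:
        L = cholesky(C_S, lower=True)
    except np.linalg.LinAlgError:
        lam = ridge_scale * np.trace(C_S) / P
        logger.warning(
            "species covariance singular for %s; applying ridge %.3g", species, lam
        )
        C_S = C_S + lam * np.eye(P)
        L = cholesky(C_S, lower=True)

    norm_m = float(np.linalg.norm(m))
    if norm_m > 1e-12:
        y = m / norm_m
    else:  # pure-specialization model: no displacement, pick axis 1
        y = np.zeros(P)
        y[0] = 1.0

    # Whiten by C_S: in b = L' a coordinates the Rayleigh quotient becomes
    # (b' Mw b) / (b' b) with Mw = L^-1 C_G L^-T.
    Li = solve_triangular(L, np.eye(P), lower=True)
    Mw = Li @ C_G @ Li.T
    Mw = (Mw + Mw.T) / 2

    rho = np.empty(P)
    rho[0] = float(y @ C_G @ y) / float(y @ C_S @ y)

    axes = np.empty((P, P))
    axes[:, 0] = y
    if P > 1:
        b_y = L.T @ y
        b_y = b_y / np.linalg.norm(b_y)
        Proj = np.eye(P) - np.outer(b_y, b_y)
        Mp = Proj @ Mw @ Proj
        Mp = (Mp + Mp.T) / 2
        evals, evecs = eigh(Mp)
        order = np.argsort(evals)[::-1][: P - 1]  # drop the projected-out axis
        rho[1:] = evals[order]
        B = evecs[:, order]
        A = solve_triangular(L.T, B, lower=False)  # back to variable space
        A /= np.linalg.norm(A, axis=0)
        axes[:, 1:] = A

    # deterministic sign convention: largest-magnitude loading positive
    flip = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(P)])
    flip[flip == 0] = 1.0
    axes *= flip

    w = np.abs(axes)
    s = w @ rho
    return NicheModel(
        species=species,
        variables=list(stack.variables),
        m=m,
        w=w,
        rho=rho,
        s=s,
        M=total_marginality(m),
        S=total_sensitivity(s),
        loadings=axes,
    )


def total_marginality(m: np.ndarray, legacy_divisor: bool = False) -> float:
    """Total marginality ``M = ||m||_2``.

    ``legacy_divisor`` divides by 1.96, the convention of some earlier
    niche-factor software that expresses M relative to a 95% normal range.
    """
    M = float(np.linalg.norm(np.asarray(m, dtype=float)))
    return M / 1.96 if legacy_divisor else M


def total_sensitivity(s: np.ndarray, method: str = "rms") -> float:
    """Total sensitivity from the per-variable factors.

    ``rms`` (default) is the square root of the mean factor,
    ``S = sqrt(mean(s_i))`` — the aggregation consistent with published
    CNFA factor tables, where the printed total is the root of the mean
    of the printed per-variable factors.  ``mean`` gives the flat mean.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty sensitivity factor vector")
    if np.any(s < 0):
        raise ValueError("sensitivity factors must be nonnegative")
    if method == "rms":
        return float(np.sqrt(s.mean()))
    if method == "mean":
        return float(s.mean())
    raise ValueError(f"unknown aggregation method {method!r}")
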