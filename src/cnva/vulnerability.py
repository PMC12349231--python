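"""Vulnerability: combining sensitivity and exposure across species.

Sensitivity factors have a much wider numeric range than exposure
factors, so raw combination lets sensitivity dominate.  The remedy used
here is max-min normalization over a *pool*: the sensitivity factors of
all species form one pool, and the exposure factors of all species
across the configured scenarios form another (optionally one pool per
scenario).  Pooled minima map to 0 and maxima to 1, preserving order.

Two combination modes are provided and both are reported:

* **normalized** (default) — ``V = (1/P) sum_j (1 + d'_j) s'_j`` on the
  pool-normalized factors, the scale-balanced total;
* **classic** — ``V = sqrt((1/P) sum_j (1 + d_j) s_j)`` on the raw
  factors, the root-mean aggregate consistent with the per-variable
  factor ``v_j = sqrt((1 + d_j) s_j)`` printed in factor tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnfa import total_sensitivity
from .exposure import total_exposure

__all__ = [
    "SpeciesAssessment",
    "AssessmentCollection",
    "vulnerability_factors",
    "normalize_pool",
    "total_vulnerability",
    "rank_species",
]


def vulnerability_factors(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Per-variable vulnerability ``v_j = sqrt((1 + d_j) s_j)``.

    Monotone increasing in both arguments; zero sensitivity gives zero
    vulnerability regardless of exposure.
    """
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    if s.shape != d.shape:
        raise ValueError(f"length mismatch: s has shape {s.shape}, d has {d.shape}")
    if np.any(s < 0) or np.any(d < 0):
        raise ValueError("sensitivity and exposure factors must be nonnegative")
    return np.sqrt((1.0 + d) * s)


@dataclass
class SpeciesAssessment:
    """Per-species factors: sensitivity plus per-scenario exposure."""

    species: str
    variables: list[str]
    s: np.ndarray  # sensitivity factors, length P
    d: dict[str, np.ndarray]  # scenario -> exposure factors, length P
    red_list: str | None = None  # e.g. "NT" / "LC"; metadata only

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        P = len(self.variables)
        if self.s.shape != (P,):
            raise ValueError(f"{self.species}: expected {P} sensitivity factors")
        self.d = {k: np.asarray(v, dtype=float) for k, v in self.d.items()}
        for scen, vec in self.d.items():
            if vec.shape != (P,):
                raise ValueError(
                    f"{self.species}/{scen}: expected {P} exposure factors"
                )

    @property
    def scenarios(self) -> list[str]:
        return list(self.d)


@dataclass
class AssessmentCollection:
    """Species assessments sharing one background and normalization pool."""

    assessments: list[SpeciesAssessment]
    per_scenario_pool: bool = False

    def __post_init__(self) -> None:
        if not self.assessments:
            raise ValueError("empty assessment collection")
        ref = self.assessments[0]
        for a in self.assessments[1:]:
            if a.variables != ref.variables:
                raise ValueError(f"{a.species} has a different variable set")
            if set(a.scenarios) != set(ref.scenarios):
                raise ValueError(f"{a.species} has a different scenario set")

    @property
    def variables(self) -> list[str]:
        return self.assessments[0].variables

    @property
    def scenarios(self) -> list[str]:
        return self.assessments[0].scenarios

    def pooled_extrema(self) -> dict:
        """Extrema of the pools: sensitivity across species; exposure
        across species and (unless ``per_scenario_pool``) scenarios."""
        s_all = np.concatenate([a.s for a in self.assessments])
        out = {"s": (float(s_all.min()), float(s_all.max()))}
        if self.per_scenario_pool:
            for scen in self.scenarios:
                d_all = np.concatenate([a.d[scen] for a in self.assessments])
                out[("d", scen)] = (float(d_all.min()), float(d_all.max()))
        else:
            d_all = np.concatenate(
                [a.d[scen] for a in self.assessments for scen in self.scenarios]
            )
            for scen in self.scenarios:
                out[("d", scen)] = (float(d_all.min()), float(d_all.max()))
        return out


def _scale(x: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    if hi <= lo:
        raise ValueError(f"degenerate normalization pool for {what}: max == min")
    return (x - lo) / (hi - lo)


def normalize_pool(collection: AssessmentCollection) -> dict:
    """Max-min normalize every species' factors against the pooled extrema.

    Returns ``{species: {"s": s', "d": {scenario: d'}}}`` with all values
    in [0, 1]; pooled min maps to 0 and pooled max to 1, order preserved.
    """
    ext = collection.pooled_extrema()
    s_lo, s_hi = ext["s"]
    out = {}
    for a in collection.assessments:
        d_norm = {}
        for scen in collection.scenarios:
            d_lo, d_hi = ext[("d", scen)]
            d_norm[scen] = _scale(a.d[scen], d_lo, d_hi, f"exposure ({scen})")
        out[a.species] = {"s": _scale(a.s, s_lo, s_hi, "sensitivity"), "d": d_norm}
    return out


def total_vulnerability(s: np.ndarray, d: np.ndarray, mode: str = "normalized") -> float:
    """Total vulnerability from per-variable factors.

    ``normalized`` expects pool-normalized factors and returns the linear
    mean ``(1/P) sum (1 + d') s'``; ``classic`` expects raw factors and
    returns ``sqrt((1/P) sum (1 + d) s)``.  Factors from different
    normalization pools must not be mixed.
    """
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    if s.shape != d.shape:
        raise ValueError("sensitivity and exposure factor lengths differ")
    if mode == "normalized":
        return float(np.mean((1.0 + d) * s))
    if mode == "classic":
        return float(np.sqrt(np.mean((1.0 + d) * s)))
    raise ValueError(f"unknown vulnerability mode {mode!r}")


def rank_species(
    collection: AssessmentCollection, mode: str = "normalized"
) -> pd.DataFrame:
    """Totals per species and scenario, sorted by V descending.

    Ties are broken by total sensitivity S, then total exposure D.
    Red-list tags are carried through for comparison narratives.
    """
    norm = normalize_pool(collection) if mode == "normalized" else None
    rows = []
    for a in collection.assessments:
        S = total_sensitivity(a.s)
        for scen in collection.scenarios:
            D = total_exposure(a.d[scen])
            if mode == "normalized":
                V = total_vulnerability(
                    norm[a.species]["s"], norm[a.species]["d"][scen], mode
                )
            else:
                V = total_vulnerability(a.s, a.d[scen], mode)
            rows.append(
                {
                    "species": a.species,
                    "scenario": scen,
                    "red_list": a.red_list,
                    "S": S,
                    "D": D,
                    "V": V,
                    "mode": mode,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["scenario", "V", "S", "D"], ascending=[True, False, False, False]
    ).reset_index(drop=True)
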