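"""Occurrence-record cleaning and spatial thinning.

Raw occurrence tables (``species, lon, lat, year, source``) are cleaned
of incomplete, duplicate, out-of-range and pre-cutoff records, then
thinned so that no two retained records of the same species lie within a
fixed radius of each other.  Thinning is a greedy pass in a documented
stable order (year ascending, then longitude, then latitude): a record
is retained iff its great-circle distance to every previously retained
record exceeds the radius.  Greedy thinning is order-dependent; fixing
the order makes it deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_KM, GridSpec

__all__ = [
    "REQUIRED_COLUMNS",
    "NoUsableRecordsError",
    "haversine_km",
    "clean_records",
    "thin_records",
    "drop_urban_records",
]

REQUIRED_COLUMNS = ["species", "lon", "lat", "year", "source"]


class NoUsableRecordsError(ValueError):
    """Cleaning or thinning left a species with no usable records."""


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def clean_records(raw: pd.DataFrame, min_year: int = 1950) -> pd.DataFrame:
    """Drop incomplete, invalid, duplicate and pre-``min_year`` records.

    Removes records with missing coordinates or year, coordinates outside
    valid lon/lat ranges, exact ``(species, lon, lat)`` duplicates (first
    kept) and records with ``year < min_year``.  Row order of survivors
    is preserved.  Raises :class:`NoUsableRecordsError` naming any
    species whose records are all removed.
    """
    missing = [c for c in ("species", "lon", "lat", "year") if c not in raw.columns]
    if missing:
        raise ValueError(f"occurrence table lacks required columns: {missing}")
    species_in = raw["species"].dropna().unique()

    df = raw.dropna(subset=["lon", "lat", "year"])
    df = df[
        df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
        & (df["year"] >= min_year)
    ]
    df = df.drop_duplicates(subset=["species", "lon", "lat"], keep="first")

    lost = sorted(set(species_in) - set(df["species"].unique()))
    if lost:
        raise NoUsableRecordsError(
            f"no usable records remain for species: {', '.join(map(str, lost))}"
        )
    return df.reset_index(drop=True)


def _thin_one(df: pd.DataFrame, radius_km: float) -> pd.DataFrame:
    ordered = df.sort_values(["year", "lon", "lat"], kind="mergesort")
    lon = ordered["lon"].to_numpy(float)
    lat = ordered["lat"].to_numpy(float)
    kept: list[int] = []
    for i in range(len(ordered)):
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[kept], lat[kept])
        if np.all(d > radius_km):
            kept.append(i)
    return ordered.iloc[kept]


def thin_records(occ: pd.DataFrame, radius_km: float = 5.0) -> pd.DataFrame:
    """Greedy spatial thinning per species at the given radius in km.

    Retained records are pairwise separated by more than ``radius_km``.
    A single record passes through unchanged.
    """
    if not radius_km > 0:
        raise ValueError("radius_km must be positive")
    parts = [
        _thin_one(group, radius_km) for _, group in occ.groupby("species", sort=False)
    ]
    if not parts:
        return occ.copy()
    return pd.concat(parts).reset_index(drop=True)


def drop_urban_records(
    occ: pd.DataFrame,
    footprint: np.ndarray,
    grid: GridSpec,
    quantile: float = 0.99,
) -> pd.DataFrame:
    """Drop records in cells where the footprint exceeds the given quantile.

    A pragmatic stand-in for excluding records from urban centers: cells
    above the ``quantile`` of the footprint raster are treated as urban.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    cut = np.quantile(footprint, quantile)
    inside = grid.contains(occ["lon"], occ["lat"])
    rows, cols = grid.cell_of(occ["lon"], occ["lat"])
    urban = inside & (footprint[rows, cols] > cut)
    return occ[~urban].reset_index(drop=True)
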