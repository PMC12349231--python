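"""End-to-end assessment pipeline and run manifests.

``run_pipeline`` executes the full chain — occurrence cleaning and
thinning, range estimation, climate preparation, niche-factor fitting,
exposure, pooled vulnerability, spatial surfaces, and the conservation
overlay — from one configuration, either on a generated synthetic world
or on files on disk.  Every stage seed is derived from the single global
seed by stable hashing, so partial reruns are reproducible, and the run
manifest records inputs, parameters and output checksums.

The combined multi-species background ("global distribution") is the
union of all species ranges; background statistics for standardization
and the global covariance are computed over those cells.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnfa import fit_cnfa, total_marginality
from .conservation import coverage_by_class, couple_footprint, pa_coverage
from .exposure import departure
from .io import (
    read_ascii_grid,
    read_geojson,
    read_occurrences,
    write_ascii_grid,
    write_geojson,
    write_occurrences,
)
from .occurrences import clean_records, thin_records
from .prep import select_variables, standardize
from .ranges import estimate_range_idw, habitat_weights, occurrence_weights
from .stack import ClimateStack
from .surfaces import exposure_surface, sensitivity_surface, vulnerability_surface
from .synthetic import (
    SpeciesSpec,
    WorldSpec,
    generate_climate,
    generate_footprint,
    generate_protected_areas,
    generate_species,
)
from .vulnerability import (
    AssessmentCollection,
    SpeciesAssessment,
    rank_species,
    vulnerability_factors,
)

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "stage_seed",
    "simulate_world",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries stage name and species context."""


def stage_seed(global_seed: int, stage: str, name: str = "") -> int:
    """Deterministic per-stage seed fan-out by stable hashing (CRC32)."""
    return zlib.crc32(f"{global_seed}:{stage}:{name}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """One configuration for a full pipeline run.

    Either ``world`` (plus ``species``) describes a synthetic world, or
    ``data`` points at input files: ``occurrences`` (CSV),
    ``current``/``futures`` (ASCII-grid raster per variable, futures
    keyed by scenario), ``protected_areas`` (GeoJSON), ``footprint``
    (ASCII grid).
    """

    seed: int = 0
    world: dict | None = None
    species: list[dict] = field(default_factory=list)
    data: dict | None = None
    min_year: int = 1950
    thin_radius_km: float = 5.0
    idw_power: float = 2.0
    idw_threshold: float = 0.5
    idw_n_pseudoabs: int | None = None
    weights_mode: str = "uniform"  # uniform | score | occurrences
    auto_select_variables: bool = True
    r_threshold: float = 0.7
    pa_coverage_fraction: float = 0.15
    pa_n_polygons: int = 8
    footprint_hotspots: int = 3
    coupling_alpha: float = 0.5
    per_scenario_pool: bool = False

    def __post_init__(self) -> None:
        if self.world is None and self.data is None:
            raise ValueError("config needs either a synthetic 'world' or 'data' paths")
        if self.world is not None and not self.species:
            raise ValueError("synthetic mode requires at least one species spec")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _with_mask(stack: ClimateStack, mask: np.ndarray) -> ClimateStack:
    values = np.where(mask[None, :, :], stack.values, np.nan)
    return ClimateStack(
        grid=stack.grid,
        variables=list(stack.variables),
        values=values,
        mask=mask,
        label=stack.label,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_world(config: RunConfig, out_dir) -> dict:
    """Generate a complete synthetic world and write it to a directory."""
    if config.world is None:
        raise ValueError("simulate_world requires a synthetic world config")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wspec = WorldSpec(**{**config.world, "seed": config.world.get("seed", config.seed)})
    current, futures = generate_climate(wspec)
    grid = wspec.grid

    frames = []
    for i, sp in enumerate(config.species):
        sspec = SpeciesSpec(
            **{**sp, "seed": sp.get("seed", stage_seed(config.seed, "species", sp.get("name", str(i))))}
        )
        frames.append(generate_species(sspec, current))
    occ = pd.concat(frames, ignore_index=True)

    pas = generate_protected_areas(
        grid,
        config.pa_coverage_fraction,
        config.pa_n_polygons,
        seed=stage_seed(config.seed, "pa"),
    )
    fp = generate_footprint(
        grid, config.footprint_hotspots, seed=stage_seed(config.seed, "footprint")
    )

    write_occurrences(out / "occurrences.csv", occ)
    for stack in [current, *futures.values()]:
        for j, var in enumerate(stack.variables):
            write_ascii_grid(out / f"climate_{stack.label}_{var}.asc", stack.values[j], grid)
    write_geojson(out / "protected_areas.geojson", pas)
    write_ascii_grid(out / "footprint.asc", fp, grid)
    return {
        "grid": grid,
        "current": current,
        "futures": futures,
        "occurrences": occ,
        "protected_areas": pas,
        "footprint": fp,
    }


def _load_inputs(config: RunConfig) -> dict:
    """Acquire pipeline inputs, synthetically or from configured paths."""
    if config.world is not None:
        wspec = WorldSpec(**{**config.world, "seed": config.world.get("seed", config.seed)})
        current, futures = generate_climate(wspec)
        occ = pd.concat(
            [
                generate_species(
                    SpeciesSpec(
                        **{
                            **sp,
                            "seed": sp.get(
                                "seed",
                                stage_seed(config.seed, "species", sp.get("name", str(i))),
                            ),
                        }
                    ),
                    current,
                )
                for i, sp in enumerate(config.species)
            ],
            ignore_index=True,
        )
        pas = generate_protected_areas(
            wspec.grid,
            config.pa_coverage_fraction,
            config.pa_n_polygons,
            seed=stage_seed(config.seed, "pa"),
        )
        fp = generate_footprint(
            wspec.grid, config.footprint_hotspots, seed=stage_seed(config.seed, "footprint")
        )
        return {
            "current": current,
            "futures": futures,
            "occurrences": occ,
            "protected_areas": pas,
            "footprint": fp,
            "footprint_grid": wspec.grid,
        }

    d = config.data
    occ = read_occurrences(d["occurrences"])

    def load_stack(paths: dict, label: str) -> ClimateStack:
        variables, layers, grid = [], [], None
        for var, p in paths.items():
            vals, g = read_ascii_grid(p)
            grid = grid or g
            if g != grid:
                raise ValueError(f"raster {p} is not on the shared grid")
            variables.append(var)
            layers.append(vals)
        values = np.stack(layers)
        mask = np.all(np.isfinite(values), axis=0)
        return ClimateStack(
            grid=grid, variables=variables, values=values, mask=mask, label=label
        )

    current = load_stack(d["current"], "current")
    futures = {
        scen: load_stack(paths, scen) for scen, paths in d["futures"].items()
    }
    pas = read_geojson(d["protected_areas"]) if d.get("protected_areas") else []
    fp, fp_grid = (
        read_ascii_grid(d["footprint"]) if d.get("footprint") else (None, None)
    )
    return {
        "current": current,
        "futures": futures,
        "occurrences": occ,
        "protected_areas": pas,
        "footprint": fp,
        "footprint_grid": fp_grid,
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage in order and write tables, rasters and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config)
    current_raw: ClimateStack = inputs["current"]
    futures_raw: dict[str, ClimateStack] = inputs["futures"]
    grid = current_raw.grid

    # --- occurrences: clean and thin, per species -----------------------
    occ = clean_records(inputs["occurrences"], min_year=config.min_year)
    occ = thin_records(occ, radius_km=config.thin_radius_km)
    species_names = list(dict.fromkeys(occ["species"]))

    # --- ranges and habitat weights ------------------------------------
    ranges, weights = {}, {}
    for name in species_names:
        sub = occ[occ["species"] == name]
        try:
            rng_est = estimate_range_idw(
                sub,
                grid,
                current_raw.mask,
                power=config.idw_power,
                n_pseudoabs=config.idw_n_pseudoabs,
                threshold=config.idw_threshold,
                seed=stage_seed(config.seed, "range", name),
                buffer_km=config.thin_radius_km,
            )
            ranges[name] = rng_est
            if config.weights_mode == "occurrences":
                weights[name] = occurrence_weights(sub, grid, rng_est.in_range)
            else:
                weights[name] = habitat_weights(rng_est, mode=config.weights_mode)
        except Exception as exc:
            raise PipelineStageError(
                f"stage 'range' failed for species {name!r}: {exc}"
            ) from exc

    # --- combined background and climate preparation --------------------
    combined = np.zeros(grid.shape, dtype=bool)
    for rng_est in ranges.values():
        combined |= rng_est.in_range
    current_bg = _with_mask(current_raw, combined)
    if config.auto_select_variables:
        kept = select_variables(current_bg, r_threshold=config.r_threshold)
    else:
        kept = list(current_bg.variables)
    current_std = standardize(current_bg.select(kept))
    futures_std = {
        scen: standardize(_with_mask(f, combined).select(kept), reference=current_std)
        for scen, f in futures_raw.items()
    }
    scenarios = sorted(futures_std)

    # --- fit, exposure, vulnerability -----------------------------------
    models, assessments = {}, []
    for name in species_names:
        try:
            model = fit_cnfa(current_std, weights[name], species=name)
            d = {
                scen: departure(
                    current_std, futures_std[scen], weights[name], species=name
                ).d
                for scen in scenarios
            }
        except Exception as exc:
            raise PipelineStageError(
                f"stage 'fit/exposure' failed for species {name!r}: {exc}"
            ) from exc
        models[name] = model
        assessments.append(
            SpeciesAssessment(species=name, variables=kept, s=model.s, d=d)
        )
    collection = AssessmentCollection(assessments, per_scenario_pool=config.per_scenario_pool)

    factor_rows = []
    for a in assessments:
        for j, var in enumerate(kept):
            row = {"species": a.species, "variable": var, "s": a.s[j]}
            for scen in scenarios:
                row[f"d_{scen}"] = a.d[scen][j]
                row[f"v_{scen}"] = float(vulnerability_factors(a.s, a.d[scen])[j])
            factor_rows.append(row)
    factors_df = pd.DataFrame(factor_rows)

    totals_norm = rank_species(collection, mode="normalized")
    totals_classic = rank_species(collection, mode="classic")
    totals_df = totals_norm.merge(
        totals_classic[["species", "scenario", "V"]].rename(columns={"V": "V_classic"}),
        on=["species", "scenario"],
    )
    totals_df["M"] = [total_marginality(models[n].m) for n in totals_df["species"]]

    # --- surfaces and conservation overlay ------------------------------
    pas = inputs["protected_areas"]
    fp = inputs["footprint"]
    summary_rows = []
    for name in species_names:
        try:
            sens = sensitivity_surface(models[name], current_std, ranges[name])
        except Exception as exc:
            raise PipelineStageError(
                f"stage 'surfaces' failed for species {name!r}: {exc}"
            ) from exc
        write_ascii_grid(out / f"sensitivity_{name}.asc", sens.values, grid)
        for scen in scenarios:
            expo = exposure_surface(
                current_std, futures_std[scen], ranges[name], species=name
            )
            vuln = vulnerability_surface(sens, expo)
            write_ascii_grid(out / f"vulnerability_{name}_{scen}.asc", vuln.values, grid)
            write_ascii_grid(
                out / f"vulnerability_class_{name}_{scen}.asc",
                vuln.classes.astype(float),
                grid,
            )
            summary = coverage_by_class(vuln, pas, footprint=fp)
            row = summary.as_row()
            row["pa_range_total"] = pa_coverage(ranges[name], pas)
            if fp is not None:
                coupled, _ = couple_footprint(
                    vuln, fp, inputs["footprint_grid"], alpha=config.coupling_alpha
                )
                row["coupled_mean"] = float(
                    np.nanmean(coupled.values[coupled.in_range])
                )
            summary_rows.append(row)
    shares_df = pd.DataFrame(summary_rows)

    factors_df.to_csv(out / "factors.csv", index=False)
    totals_df.to_csv(out / "totals.csv", index=False)
    shares_df.to_csv(out / "class_shares.csv", index=False)
    if pas:
        write_geojson(out / "protected_areas.geojson", pas)

    # --- manifest --------------------------------------------------------
    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "variables": kept,
        "scenarios": scenarios,
        "species": species_names,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
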