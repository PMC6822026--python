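"""Occurrence I/O, accuracy filtering, configuration and orchestration.

The occurrence dialect is a delimited text table with header
``species_id, locality_id, x_km, y_km, accuracy_km, in_study_area`` on
projected planar km coordinates.  Records whose positional accuracy is
worse than the threshold (default 6 km; the boundary is inclusive, i.e.
accuracy exactly 6 km is kept) are dropped and counted.

:func:`run_pipeline` chains the stages — range metrics, gridded richness,
stepwise reconstruction, richness GLMs with spatial filtering, and SRC
composition — under one config with explicit seeds, so identical
(input, config) reruns produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grid as gridmod
from . import ranges, reconstruction, spatial

__all__ = [
    "RejectionLog",
    "PipelineConfig",
    "PipelineResult",
    "read_occurrences",
    "write_occurrences",
    "run_pipeline",
]

REQUIRED_COLUMNS = ["species_id", "locality_id", "x_km", "y_km", "accuracy_km", "in_study_area"]


@dataclass
class RejectionLog:
    """Bookkeeping for one occurrence file read.

    Invariant: n_kept + n_dropped_accuracy + n_dropped_duplicate == n_input.
    """

    n_input: int = 0
    n_kept: int = 0
    n_dropped_accuracy: int = 0
    n_dropped_duplicate: int = 0
    warnings: list = field(default_factory=list)


def read_occurrences(path, accuracy_max_km: float = 6.0):
    """Read and validate an occurrence table.

    Drops records with ``accuracy_km > accuracy_max_km`` (boundary
    inclusive: accuracy exactly at the threshold is kept) and collapses
    duplicate (species_id, locality_id) rows with a warning.  Parse
    problems are reported with 1-based data line numbers.

    Returns (records DataFrame, RejectionLog).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    log = RejectionLog(n_input=len(df))

    for col in ("x_km", "y_km", "accuracy_km"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric {col} at line(s) {lines[:10]}")
        if coerced.isna().any():
            lines = (df.index[coerced.isna()] + 2).tolist()
            raise ValueError(f"{path}: missing {col} at line(s) {lines[:10]}")
        df[col] = coerced
    if df["accuracy_km"].lt(0).any():
        raise ValueError(f"{path}: negative accuracy_km")
    df["in_study_area"] = df["in_study_area"].astype(bool)

    keep = df["accuracy_km"] <= accuracy_max_km
    log.n_dropped_accuracy = int((~keep).sum())
    df = df[keep]

    dup = df.duplicated(subset=["species_id", "locality_id"], keep="first")
    log.n_dropped_duplicate = int(dup.sum())
    if log.n_dropped_duplicate:
        msg = f"collapsed {log.n_dropped_duplicate} duplicate (species, locality) rows"
        log.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
        df = df[~dup]

    df = df.reset_index(drop=True)
    log.n_kept = len(df)
    return df, log


def write_occurrences(records: pd.DataFrame, path) -> None:
    """Write an occurrence table in the package dialect."""
    records.to_csv(path, index=False, columns=REQUIRED_COLUMNS)


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults reproduce the standard protocol
    (20 km cells, 6 km accuracy filter, 10,000 randomizations, 14 distance
    classes, 59 km truncation)."""

    cell_size_km: float = 20.0
    grid_origin: tuple | None = None  # (x, y); None = snap to data
    accuracy_max_km: float = 6.0
    class_thresholds: tuple = (0.85, 0.60, 0.40, 0.20)
    # reconstruction
    n_randomizations: int = 10_000  # tie-randomized replicates per median curve
    n_null: int = 10_000  # random-order null replicates
    tie_policy: str = "all"
    cell_policy: str = "all"  # cells entering tau: "all" occupied or "subset"
    crossing_threshold: float = 0.5
    # GLM / spatial
    family_rare: str = "negative_binomial"
    family_common: str = "poisson"
    alpha: float = 0.05
    truncation_km: float = 59.0
    n_distance_classes: int = 14
    n_permutations: int = 10_000
    select_spatial_filters: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_origin" in raw and raw["grid_origin"] is not None:
            raw["grid_origin"] = tuple(raw["grid_origin"])
        if "class_thresholds" in raw:
            raw["class_thresholds"] = tuple(raw["class_thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    profiles: pd.DataFrame
    rsfd: dict
    surface: gridmod.RichnessSurface
    classification: gridmod.RichnessClassification
    hotspot_cells: set
    src_cells: set
    curves: dict  # direction -> SubsetCurve
    null: reconstruction.NullModel
    crossings: dict
    glm_reports: pd.DataFrame
    glm_fits: dict
    correlograms: dict
    composition_per_cell: pd.DataFrame
    composition_summary: pd.DataFrame
    manifest: dict


def _richness_by_quartile(surface, profiles, quartile):
    spp = set(profiles.loc[profiles["rarity_quartile"] == quartile, "species_id"])
    cells = surface.cells
    return np.array(
        [len(surface.cell_species[c] & spp) for c in cells], dtype=float
    )


def run_pipeline(config: PipelineConfig, records: pd.DataFrame) -> PipelineResult:
    """Execute the full analysis on validated occurrence records.

    Stages run in order: range metrics -> gridded richness -> stepwise
    reconstruction -> richness GLMs (nonspatial + spatially filtered) ->
    SRC composition.  Every randomized stage uses an independent stream
    derived from ``config.seed``, so the run is fully deterministic.
    """
    seed = int(config.seed)

    def stream(i: int) -> np.random.Generator:
        return np.random.default_rng([seed, i])

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- range metrics (all records, including out-of-area) -------------
    def _ranges():
        profiles = ranges.assign_quartiles(ranges.species_profiles(records))
        return profiles, ranges.rsfd_summary(profiles)

    profiles, rsfd = stage("range_metrics", _ranges)

    # --- gridded richness -----------------------------------------------
    def _grid():
        if config.grid_origin is not None:
            inside = records[records["in_study_area"].astype(bool)]
            ox, oy = config.grid_origin
            s = config.cell_size_km
            n_cols = int(np.floor((inside["x_km"].max() - ox) / s)) + 1
            n_rows = int(np.floor((inside["y_km"].max() - oy) / s)) + 1
            g = gridmod.GridSpec(ox, oy, s, n_cols, n_rows)
        else:
            g = gridmod.GridSpec.covering(records, config.cell_size_km)
        surf = gridmod.richness_surface(records, g)
        cls = gridmod.classify_richness(surf, config.class_thresholds)
        return surf, cls

    surface, classification = stage("grid_richness", _grid)
    hot = gridmod.hotspots(classification)
    src = gridmod.srcs(classification)

    # --- stepwise reconstruction ----------------------------------------
    def _reconstruct():
        cells, overall, species_cells = surface.species_cell_indices()
        in_grid = profiles[profiles["species_id"].isin(species_cells)].reset_index(drop=True)
        curves = {}
        for i, direction in enumerate(("ascending", "descending")):
            curves[direction] = reconstruction.median_curve(
                in_grid,
                species_cells,
                overall,
                direction,
                n_randomizations=config.n_randomizations,
                rng=stream(10 + i),
                tie_policy=config.tie_policy,
                cells=config.cell_policy,
            )
        null = reconstruction.null_model(
            in_grid,
            species_cells,
            overall,
            n_replicates=config.n_null,
            rng=stream(12),
            cells=config.cell_policy,
        )
        crossings = {}
        for direction, curve in curves.items():
            reconstruction.attach_empirical_p(curve, null)
            crossings[direction] = reconstruction.crossing_point(
                curve, config.crossing_threshold
            )
        return curves, null, crossings

    curves, null, crossings = stage("reconstruction", _reconstruct)

    # --- GLMs with spatial filtering -------------------------------------
    def _glm():
        cells = surface.cells
        coords = np.array([surface.grid.cell_center(c) for c in cells])
        y = surface.richness_vector(cells)
        fits, cors, rows = {}, {}, []
        fset = (
            spatial.pcnm_filters(coords, config.truncation_km)
            if config.select_spatial_filters
            else None
        )
        for name, quartile, family in (
            ("rare", 1, config.family_rare),
            ("common", 4, config.family_common),
        ):
            x = _richness_by_quartile(surface, profiles, quartile)
            X = pd.DataFrame({"intercept": np.ones_like(y), name: x})
            fit = spatial.fit_glm(y, X, family)
            cor = spatial.morans_i_correlogram(
                fit.residuals,
                coords,
                n_classes=config.n_distance_classes,
                n_permutations=config.n_permutations,
                rng=stream(20),
            )
            fits[(name, "nonspatial")] = fit
            cors[(name, "nonspatial")] = cor
            rows.append((name, family, "nonspatial", 0, fit.pseudo_r2, fit.aicc))
            if config.select_spatial_filters:
                sel, sfit, scor, status = spatial.select_filters(
                    y,
                    X,
                    fset,
                    family,
                    coords,
                    alpha=config.alpha,
                    n_classes=config.n_distance_classes,
                    n_permutations=config.n_permutations,
                    rng=stream(21),
                )
                fits[(name, "spatial")] = sfit
                cors[(name, "spatial")] = scor
                rows.append(
                    (name, family, "spatial", len(sel.selected), sfit.pseudo_r2, sfit.aicc)
                )
        report = pd.DataFrame(
            rows,
            columns=["predictor", "family", "model", "n_filters", "pseudo_r2", "aicc"],
        )
        return fits, cors, report

    glm_fits, correlograms, glm_reports = stage("spatial_glm", _glm)

    # --- SRC composition --------------------------------------------------
    def _compose():
        quartile_of = dict(zip(profiles["species_id"], profiles["rarity_quartile"]))
        return gridmod.src_composition(src, quartile_of, surface.cell_species)

    composition_per_cell, composition_summary = stage("src_composition", _compose)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "n_records": int(len(records)),
        "n_species": int(profiles.shape[0]),
        "n_occupied_cells": len(surface.cells),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return PipelineResult(
        profiles=profiles,
        rsfd=rsfd,
        surface=surface,
        classification=classification,
        hotspot_cells=hot,
        src_cells=src,
        curves=curves,
        null=null,
        crossings=crossings,
        glm_reports=glm_reports,
        glm_fits=glm_fits,
        correlograms=correlograms,
        composition_per_cell=composition_per_cell,
        composition_summary=composition_summary,
        manifest=manifest,
    )


def write_results(result: PipelineResult, out_dir) -> list:
    """Write all result tables and the run manifest; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    _write(result.profiles, "species_profiles.csv")
    _write(result.classification.to_frame(), "richness_classification.csv")
    curve_frames = []
    for direction, curve in result.curves.items():
        df = curve.to_frame()
        nf = result.null.to_frame()
        curve_frames.append(df.merge(nf, on="k"))
    _write(pd.concat(curve_frames, ignore_index=True), "curves.csv")
    _write(result.glm_reports, "glm_report.csv")
    for key, cor in result.correlograms.items():
        _write(cor.to_frame(), f"correlogram_{key[0]}_{key[1]}.csv")
    _write(result.composition_per_cell, "src_composition.csv")
    _write(result.composition_summary, "src_composition_summary.csv")
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
    written.append(mpath)
    return written
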