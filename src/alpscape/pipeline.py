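"""End-to-end orchestration: synthesize -> ABM -> run selection -> climate
-> SDM -> range metrics -> mixed-model stats.

One config and one root seed drive the whole chain; every stage writes its
artifacts (rasters, CSV tables) under the output directory together with a
manifest carrying the config hash and seed, so a run is reproducible and
individual stages can be re-run against cached upstream outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, landuse as lu
from .abm import DecisionTable, default_timeline, run_simulation
from .climate import ClimateGrids, apply_deltas, interpolate_deltas
from .metrics import (
    classify_specialists,
    group_response,
    range_change,
    records_to_frame,
    richness_change,
)
from .rasters import write_raster
from .sdm import (
    build_region_predictors,
    evaluation_table,
    fit_species_models,
    importance_table,
    project_region,
)
from .selection import RunIndexPair, intensive_area, landuse_evenness, select_representative_runs
from .stats import fit_glmm_exposure, fit_lmm_log_ratio, partition_variance
from .synthetic import (
    ClimateConfig,
    LandscapeConfig,
    pool_config_for_climate,
    generate_climate,
    generate_farms,
    generate_landscape,
    generate_scenario_deltas,
    generate_species_pool,
    sample_plots,
)

logger = logging.getLogger(__name__)

STAGES = ("synth", "abm", "select", "climate", "sdm", "metrics", "stats")


@dataclass
class PipelineConfig:
    seed: int = 1
    rows: int = 120
    cols: int = 120
    n_farms: int = 60
    n_species: int = 50
    n_plots: int = 400
    n_years: int = 36
    n_replicates: int = 5
    n_selected: int = 5
    min_occurrences: int = 30
    climate_scenarios: List[str] = field(default_factory=lambda: ["current", "RCP8.5"])
    landuse_scenarios: List[str] = field(default_factory=lambda: ["current", "BAU"])
    specialist_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            lu.FORESTS: 0.25,
            lu.ALPINE: 0.2,
            lu.GRASSLANDS: 0.2,
            lu.AGRICULTURAL: 0.15,
        }
    )
    climate_dominant_fraction: float = 0.5
    delta_spatial_amplitude: float = 0.2
    write_annual_maps: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(seed: int = 1) -> PipelineConfig:
    """The desk-scale demonstration configuration."""
    return PipelineConfig(seed=seed)


@dataclass
class PipelineResult:
    """In-memory handles to every stage's outputs."""

    config: PipelineConfig
    outdir: Path
    landscape: object = None
    state: object = None
    climate_current: Optional[ClimateGrids] = None
    climate_future: Dict[str, ClimateGrids] = field(default_factory=dict)
    pool: list = field(default_factory=list)
    plots: object = None
    end_maps: Dict[str, List[np.ndarray]] = field(default_factory=dict)
    selected_runs: Dict[str, Dict[str, int]] = field(default_factory=dict)
    fits: list = field(default_factory=list)
    records: Optional[pd.DataFrame] = None
    specialists: Dict[str, str] = field(default_factory=dict)
    group_responses: Optional[pd.DataFrame] = None
    sdm_eval: Optional[pd.DataFrame] = None
    importances: Optional[pd.DataFrame] = None
    stats_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage_synth(cfg: PipelineConfig, res: PipelineResult) -> None:
    land_cfg = LandscapeConfig(rows=cfg.rows, cols=cfg.cols)
    res.landscape = generate_landscape(land_cfg, seed=cfg.seed)
    res.climate_current = generate_climate(res.landscape, seed=cfg.seed)
    res.state = generate_farms(res.landscape, cfg.n_farms, seed=cfg.seed)
    res.pool = generate_species_pool(
        cfg.n_species,
        cfg.specialist_fractions,
        seed=cfg.seed,
        climate_dominant_fraction=cfg.climate_dominant_fraction,
        config=pool_config_for_climate(res.climate_current),
    )
    res.plots = sample_plots(
        res.pool,
        res.landscape,
        res.climate_current,
        cfg.n_plots,
        seed=cfg.seed,
        min_occurrences=cfg.min_occurrences,
    )
    d = res.outdir / "synth"
    d.mkdir(parents=True, exist_ok=True)
    write_raster(d / "landuse_current.tif", res.landscape.landuse, res.landscape.geom)
    write_raster(d / "elevation.tif", res.landscape.elevation, res.landscape.geom)
    write_raster(d / "substrate.tif", res.landscape.substrate, res.landscape.geom)
    write_raster(d / "solar.tif", res.landscape.solar, res.landscape.geom)
    res.plots.data.to_csv(d / "plots.csv", index=False)
    pd.DataFrame(
        [
            {
                "species": n.species_id,
                "planted_group": n.planted_group or "generalist",
                "climate_dominant": n.climate_dominant,
                "bio6_optimum": n.bio_optimum["bio6"],
                "bio6_breadth": n.bio_breadth["bio6"],
                "substrate_pref": n.substrate_pref,
            }
            for n in res.pool
        ]
    ).to_csv(d / "species.csv", index=False)
    pd.DataFrame(
        [
            {"farm": f.id, "type": f.ftype, "intensity": f.intensity,
             "style": f.style, "n_parcels": len(f.owned)}
            for f in res.state.farms.values()
        ]
    ).to_csv(d / "farms.csv", index=False)


def _stage_abm(cfg: PipelineConfig, res: PipelineResult) -> None:
    d = res.outdir / "abm"
    d.mkdir(parents=True, exist_ok=True)
    table = DecisionTable.default()
    table.to_frame().to_csv(d / "decision_table.csv", index=False)
    for scen in cfg.landuse_scenarios:
        if scen == "current":
            continue
        timeline = default_timeline(scen, cfg.n_years)
        panel: list = []
        trajs = run_simulation(
            res.state,
            timeline,
            cfg.n_years,
            cfg.n_replicates,
            root_seed=cfg.seed,
            table=table,
            keep_annual=cfg.write_annual_maps,
            panel_out=panel,
        )
        end_maps = [t[-1] for t in trajs]
        res.end_maps[scen] = end_maps
        for r, m in enumerate(end_maps):
            write_raster(d / f"landuse_{scen}_rep{r}.tif", m, res.landscape.geom)
        pd.DataFrame(panel).to_csv(d / f"panel_{scen}.csv", index=False)


def _stage_select(cfg: PipelineConfig, res: PipelineResult) -> None:
    d = res.outdir / "select"
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for scen, maps in res.end_maps.items():
        pairs = [
            RunIndexPair(r, landuse_evenness(m), float(intensive_area(m)))
            for r, m in enumerate(maps)
        ]
        chosen = select_representative_runs(pairs)
        res.selected_runs[scen] = chosen
        inv = {v: k for k, v in chosen.items()}
        for p in pairs:
            rows.append(
                {
                    "scenario": scen,
                    "replicate": p.replicate,
                    "evenness": p.evenness,
                    "intensive_area": p.intensive_area,
                    "selected_role": inv.get(p.replicate, ""),
                }
            )
    pd.DataFrame(rows).to_csv(d / "selection.csv", index=False)


def _stage_climate(cfg: PipelineConfig, res: PipelineResult) -> None:
    d = res.outdir / "climate"
    d.mkdir(parents=True, exist_ok=True)
    cur = res.climate_current
    for v, arr in cur.bio().items():
        write_raster(d / f"{v}_current.tif", arr)
    for scen in cfg.climate_scenarios:
        if scen == "current":
            continue
        deltas = generate_scenario_deltas(
            scen, seed=cfg.seed, spatial_amplitude=cfg.delta_spatial_amplitude
        )
        fine = interpolate_deltas(deltas, cur.shape)
        fut = apply_deltas(cur, fine, period=scen)
        res.climate_future[scen] = fut
        for v, arr in fut.bio().items():
            write_raster(d / f"{v}_{scen.replace('.', '_')}.tif", arr)


def _stage_sdm(cfg: PipelineConfig, res: PipelineResult) -> None:
    d = res.outdir / "sdm"
    d.mkdir(parents=True, exist_ok=True)
    res.fits = []
    for sp in res.plots.usable_species():
        try:
            fit = fit_species_models(res.plots, sp, seed=cfg.seed)
        except ValueError:
            continue
        if fit.usable:
            res.fits.append(fit)
    res.sdm_eval = evaluation_table(res.fits)
    res.sdm_eval.to_csv(d / "evaluation.csv", index=False)
    res.importances = importance_table(res.fits, res.plots, seed=cfg.seed)
    res.importances.to_csv(d / "importance.csv", index=False)


def _scenario_landuse_maps(cfg: PipelineConfig, res: PipelineResult, scen: str):
    """Yield (run id, land-use map) for one land-use scenario."""
    if scen == "current":
        yield 0, res.landscape.landuse
        return
    chosen = res.selected_runs.get(scen)
    reps = sorted(set(chosen.values())) if chosen else range(len(res.end_maps[scen]))
    for r in reps:
        yield r, res.end_maps[scen][r]


def _stage_metrics(cfg: PipelineConfig, res: PipelineResult) -> None:
    d = res.outdir / "metrics"
    d.mkdir(parents=True, exist_ok=True)
    climates: Dict[str, ClimateGrids] = {"current": res.climate_current, **res.climate_future}
    base_pred = build_region_predictors(res.landscape, res.climate_current, res.landscape.landuse)
    current_maps = {
        f.species_id: project_region(
            f, res.landscape, res.climate_current, res.landscape.landuse, predictors=base_pred
        ).binary
        for f in res.fits
    }
    usable = {sp for sp, m in current_maps.items() if m.sum() > 0}
    skipped = set(current_maps) - usable
    if skipped:
        logger.info("excluding %d species with empty current range", len(skipped))

    records = []
    richness_rows = []
    for cscen in cfg.climate_scenarios:
        for lscen in cfg.landuse_scenarios:
            clim = climates[cscen]
            for run, lu_map in _scenario_landuse_maps(cfg, res, lscen):
                pred = build_region_predictors(
                    res.landscape, clim, np.asarray(lu_map)
                )
                future_stack = {}
                for f in res.fits:
                    if f.species_id not in usable:
                        continue
                    fut = project_region(
                        f, res.landscape, clim, np.asarray(lu_map), predictors=pred,
                        climate_scenario=cscen, landuse_scenario=lscen, run=run,
                    ).binary
                    future_stack[f.species_id] = fut
                    records.append(
                        range_change(
                            current_maps[f.species_id], fut, species_id=f.species_id,
                            climate_scenario=cscen, landuse_scenario=lscen, run=run,
                        )
                    )
                delta = richness_change(
                    {s: current_maps[s] for s in future_stack}, future_stack
                )
                write_raster(
                    d / f"richness_delta_{cscen.replace('.', '_')}_{lscen}_run{run}.tif",
                    delta,
                )
                richness_rows.append(
                    {
                        "climate": cscen,
                        "landuse": lscen,
                        "run": run,
                        "mean_delta": float(delta.mean()),
                        "gain_cells": int((delta > 0).sum()),
                        "loss_cells": int((delta < 0).sum()),
                    }
                )
    res.records = records_to_frame(records)
    res.records.to_csv(d / "records.csv", index=False)
    pd.DataFrame(richness_rows).to_csv(d / "richness_summary.csv", index=False)

    res.specialists = classify_specialists(res.plots)
    pd.Series(res.specialists, name="group").rename_axis("species").reset_index().to_csv(
        d / "specialists.csv", index=False
    )
    gr = []
    for group in lu.HABITAT_GROUPS:
        if any(g == group for g in res.specialists.values()):
            gr.append(group_response(res.records, res.specialists, group))
    res.group_responses = pd.concat(gr, ignore_index=True) if gr else pd.DataFrame()
    res.group_responses.to_csv(d / "group_response.csv", index=False)


def _stage_stats(cfg: PipelineConfig, res: PipelineResult) -> None:
    d = res.outdir / "stats"
    d.mkdir(parents=True, exist_ok=True)
    recs = res.records
    if recs is None or recs.empty:
        logger.warning("no records; skipping stats stage")
        return
    lmm = fit_lmm_log_ratio(recs)
    lmm.summary_frame().assign(aic=lmm.aic, rm2=lmm.rm2, rc2=lmm.rc2).to_csv(
        d / "lmm_log_ratio.csv", index=False
    )
    part = partition_variance(recs, response="log_ratio")
    part.to_csv(d / "variance_partition_log_ratio.csv", index=False)
    res.stats_tables["lmm"] = lmm.summary_frame()
    res.stats_tables["partition_log_ratio"] = part
    try:
        glmm = fit_glmm_exposure(recs)
        glmm.summary_frame().assign(aic=glmm.aic, rm2=glmm.rm2, rc2=glmm.rc2).to_csv(
            d / "glmm_exposure.csv", index=False
        )
        res.stats_tables["glmm"] = glmm.summary_frame()
    except ValueError as err:
        logger.warning("exposure GLMM skipped: %s", err)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "abm": _stage_abm,
    "select": _stage_select,
    "climate": _stage_climate,
    "sdm": _stage_sdm,
    "metrics": _stage_metrics,
    "stats": _stage_stats,
}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Run the pipeline (or a prefix-closed subset of stages) and write all
    artifacts plus a manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    res = PipelineResult(config=config, outdir=outdir)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    # stages must run in canonical order; upstream stages a subset depends on
    # are executed (cheaply regenerated from the same seed) as needed
    for s in STAGES:
        if s not in stages and not any(STAGES.index(t) > STAGES.index(s) for t in stages):
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[s](config, res)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {s!r} failed: {err}") from err
        manifest["stages"][s] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        logger.info("stage %-8s done in %.1fs", s, manifest["stages"][s]["wall_time_s"])
    config.to_yaml(outdir / "config.yaml")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return res
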