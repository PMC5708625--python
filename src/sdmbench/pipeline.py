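"""Resumable, seeded pipeline stages over the benchmark library.

The pipeline materialises the study on disk in stages —
``simulate`` (species, samples, diagnostics), ``fit`` (per-species
AUC results), ``sweep`` (configuration ladders) and ``report``
(summaries, rankings, figures) — under one output directory with a JSON
run manifest recording the resolved configuration, per-species seeds
and stage completion. Completed per-species work is skipped on resume
unless forced.

Simulated rasters are regenerated deterministically from the recorded
per-species seeds when a downstream stage needs them; the CSV artifacts
(samples, validation points, diagnostics, results) are the durable
record. Rasters requested for export are written as ESRI ASCII grids.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import (
    METHODS,
    StudyConfig,
    attach_scenarios,
    fit_species,
    simulate_species,
)
from .engines import BRTSettings, DesignSpec, GMRFSpec, MaxentFeatureSpec
from .evaluation import SweepGrid, evaluate_species, rank_methods, run_sweep, summarize_by_scenario
from .grids import GridSpec, write_esri_ascii
from .rng import derive_seed

__all__ = ["RunConfig", "load_config", "cmd_simulate", "cmd_fit_evaluate", "cmd_sweep", "cmd_report"]

DEFAULT_SWEEP_LEVELS = {
    "background_strategy": ("R", "SW", "ST", "B"),
    "covariate_reduction": (5, 2),
    "interactions": (False, True),
    "maxent_beta": (0.5, 1.0, 2.0, 4.0),
    "maxent_features": ("L", "LQ", "LQH", "LQHPT"),
    "brt_learning_rate": (0.001, 0.01, 0.1),
    "brt_tree_complexity": (1, 3, 5),
    "brt_bag_fraction": (0.5, 0.75, 1.0),
    "brt_n_trees": (250, 1000, 4000),
    "mesh_cutoff": (0.5, 1.0, 2.0, 4.0, 8.0),
}


@dataclass
class RunConfig:
    """Fully resolved run configuration (study conditions + orchestration)."""

    study: StudyConfig = field(default_factory=StudyConfig)
    n_species: int = 100
    master_seed: int = 1
    methods: tuple[str, ...] = METHODS
    outdir: str = "sdmbench_run"
    write_rasters: bool = False

    def validate(self) -> None:
        problems = []
        if self.n_species < 1:
            problems.append("n_species must be at least 1")
        if not set(self.methods) <= set(METHODS):
            problems.append(f"unknown methods {set(self.methods) - set(METHODS)}")
        if self.master_seed < 0 or self.master_seed >= 2**31:
            problems.append("master_seed must be a non-negative 31-bit integer")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (frozenset, set, tuple)):
        return sorted(_to_jsonable(v) for v in obj) if isinstance(obj, (frozenset, set)) else [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file of (nested) overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    study_raw = raw.pop("study", {})
    grid_raw = study_raw.pop("grid", None)
    kwargs = {}
    if grid_raw is not None:
        kwargs["grid"] = GridSpec(**grid_raw)
    for key, cls in (
        ("glm_design", DesignSpec),
        ("brt_design", DesignSpec),
        ("gmrf", GMRFSpec),
        ("brt", BRTSettings),
        ("maxent", MaxentFeatureSpec),
    ):
        if key in study_raw:
            sub = study_raw.pop(key)
            if key == "maxent" and "classes" in sub:
                sub["classes"] = frozenset(sub["classes"])
            kwargs[key] = cls(**sub)
    for k, v in study_raw.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    study = StudyConfig(**kwargs)
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    return RunConfig(study=study, **raw)


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "stages": {}, "species_seeds": {}, "warnings": []}

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, default=_to_jsonable))

    def stage_done(self, name: str) -> bool:
        return self.data["stages"].get(name, {}).get("done", False)

    def mark_stage(self, name: str, **info) -> None:
        self.data["stages"][name] = {"done": True, "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        self.save()


def _prepare(config: RunConfig) -> tuple[Path, _Manifest]:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    manifest.data["config"] = _to_jsonable(config)
    manifest.save()
    return outdir, manifest


def _species_seed(config: RunConfig, i: int) -> int:
    return derive_seed(config.master_seed, i)


def _load_batch(config: RunConfig, progress=None) -> list:
    batch = []
    for i in range(config.n_species):
        batch.append(
            simulate_species(config.study, _species_seed(config, i), species_id=f"sp{i:04d}")
        )
        if progress:
            progress(i + 1, config.n_species)
    return batch


def cmd_simulate(config: RunConfig, force: bool = False, log=print) -> Path:
    """Write per-species occurrence samples, validation sets and diagnostics."""
    outdir, manifest = _prepare(config)
    spdir = outdir / "species"
    spdir.mkdir(exist_ok=True)
    diag_rows = []
    for i in range(config.n_species):
        sid = f"sp{i:04d}"
        seed = _species_seed(config, i)
        manifest.data["species_seeds"][sid] = seed
        val_path = spdir / f"{sid}_validation.csv"
        if val_path.exists() and not force:
            continue
        sp = simulate_species(config.study, seed, species_id=sid)
        pd.DataFrame(
            {"x": sp.validation.points[:, 0], "y": sp.validation.points[:, 1], "label": sp.validation.labels}
        ).to_csv(val_path, index=False)
        for mode, sample in sp.samples.items():
            pd.DataFrame(
                {
                    "x": sample.points[:, 0],
                    "y": sample.points[:, 1],
                    "species_id": sid,
                    "bias_mode": mode,
                    "c": sample.clumping.c,
                }
            ).to_csv(spdir / f"{sid}_samples_{mode}.csv", index=False)
            d = sp.diagnostics[mode]
            diag_rows.append(
                {
                    "species_id": sid,
                    "bias_mode": mode,
                    "clark_evans": d.clark_evans,
                    "coverage": d.coverage,
                    "n_points": d.n_points,
                }
            )
        if config.write_rasters:
            write_esri_ascii(spdir / f"{sid}_p_clean.asc", config.study.grid, sp.truth.p_clean)
            write_esri_ascii(spdir / f"{sid}_p_noisy.asc", config.study.grid, sp.truth.p_noisy)
            write_esri_ascii(spdir / f"{sid}_reporting.asc", config.study.grid, sp.reporting.rate)
            for k in range(sp.covariates.n_cov):
                write_esri_ascii(spdir / f"{sid}_cov{k}.asc", config.study.grid, sp.covariates.layers[k])
    if diag_rows:
        diag_path = outdir / "diagnostics.csv"
        new = pd.DataFrame(diag_rows)
        if diag_path.exists() and not force:
            old = pd.read_csv(diag_path)
            new = (
                pd.concat([old, new], ignore_index=True)
                .drop_duplicates(["species_id", "bias_mode"], keep="last")
                .sort_values(["species_id", "bias_mode"])
            )
        new.to_csv(diag_path, index=False)
    manifest.mark_stage("simulate", n_species=config.n_species)
    log(f"simulate: {config.n_species} species in {outdir}")
    return outdir


def cmd_fit_evaluate(config: RunConfig, force: bool = False, log=print) -> pd.DataFrame:
    """Fit requested engines per species, write AUC results and summaries."""
    outdir, manifest = _prepare(config)
    if not manifest.stage_done("simulate"):
        raise RuntimeError("simulate stage has not completed; run cmd_simulate first")
    resdir = outdir / "results"
    resdir.mkdir(exist_ok=True)
    frames = []
    for i in range(config.n_species):
        sid = f"sp{i:04d}"
        shard = resdir / f"{sid}_auc.csv"
        if shard.exists() and not force:
            frames.append(pd.read_csv(shard))
            continue
        sp = simulate_species(config.study, _species_seed(config, i), species_id=sid)
        rows = []
        for mode in config.study.bias_modes:
            fits = fit_species(sp, mode, config.study, config.methods)
            res = evaluate_species(fits, sp.validation, species_id=sid, bias_mode=mode)
            d = sp.diagnostics[mode]
            res["clark_evans"] = d.clark_evans
            res["coverage"] = d.coverage
            res["n_points"] = d.n_points
            rows.append(res)
        pd.concat(rows, ignore_index=True).to_csv(shard, index=False)
        # aggregate from the on-disk shard so resumed and fresh runs
        # produce byte-identical tables (CSV float round-trip)
        frames.append(pd.read_csv(shard))
        log(f"fit: {sid} ({i + 1}/{config.n_species})")
    results = attach_scenarios(pd.concat(frames, ignore_index=True))
    results.to_csv(outdir / "auc_results.csv", index=False)
    manifest.mark_stage("fit", methods=list(config.methods))
    return results


def cmd_sweep(config: RunConfig, axis: str, levels=None, force: bool = False, log=print) -> pd.DataFrame:
    """Run one configuration sweep axis and write per-level results."""
    outdir, manifest = _prepare(config)
    if axis not in DEFAULT_SWEEP_LEVELS:
        raise ValueError(
            f"unknown sweep axis {axis!r}; valid axes: {sorted(DEFAULT_SWEEP_LEVELS)}"
        )
    out_path = outdir / f"sweep_{axis}.csv"
    if out_path.exists() and not force:
        log(f"sweep {axis}: reusing {out_path}")
        return pd.read_csv(out_path)
    if levels is None:
        levels = DEFAULT_SWEEP_LEVELS[axis]
    if axis == "maxent_features":
        levels = tuple(frozenset(lv) if not isinstance(lv, str) else frozenset(lv) for lv in levels)
    batch = _load_batch(config)
    sweep = SweepGrid(axis=axis, levels=tuple(levels))
    results = run_sweep(batch, sweep, config.study, methods=config.methods)
    results = attach_scenarios(results)
    results.drop(columns=["level"]).to_csv(out_path, index=False)
    manifest.mark_stage(f"sweep:{axis}", levels=[str(lv) for lv in levels])
    log(f"sweep {axis}: {len(results)} AUC rows -> {out_path}")
    return results


def cmd_report(config: RunConfig, log=print) -> pd.DataFrame:
    """Aggregate results into scenario summaries, rankings and a figure."""
    outdir, manifest = _prepare(config)
    res_path = outdir / "auc_results.csv"
    if not res_path.exists():
        raise RuntimeError("no auc_results.csv; run cmd_fit_evaluate first")
    results = pd.read_csv(res_path)
    summaries = summarize_by_scenario(results)
    ranked, top2 = rank_methods(summaries)
    ranked.to_csv(outdir / "scenario_summaries.csv", index=False)
    with open(outdir / "top2_counts.json", "w") as fh:
        json.dump(top2, fh, indent=2)
    try:
        from .evaluation import plot_scenario_summary

        plot_scenario_summary(summaries, outdir / "scenario_summary.png")
    except Exception as exc:  # plotting must never sink the report
        manifest.data["warnings"].append(f"plotting failed: {exc}")
        manifest.save()
    manifest.mark_stage("report")
    log(f"report: summaries and rankings in {outdir}")
    return ranked
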