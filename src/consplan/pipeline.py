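"""End-to-end orchestration: simulate → prep → sdm → metrics → gap → prioritize.

A single :class:`RunConfig` carries every stage parameter (defaults mirror
the analysis conventions: VIF 10, TSS 0.7, cleaning buffers 10 km / 100 m,
lock-out buffer 5 km, tiered targets 100/30/10%, BLM 0.001) plus one master
seed.  Every stochastic stage derives its own seed deterministically from
the master seed and the stage name, so a stage rerun in isolation
reproduces its part of a full pipeline run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, gap, occ, prioritize, sdm, synth
from .grids import BinaryRange, EnvStack, GridSpec, write_ascii_grid

__all__ = ["RunConfig", "PipelineRun", "run_pipeline", "stage_seed"]

logger = logging.getLogger("consplan")

_STAGES = ("simulate", "prep", "sdm", "metrics", "gap", "prioritize", "report")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults give a desk-scale but full run."""

    outdir: str = "consplan_run"
    seed: int = 0
    # landscape
    nrows: int = 60
    ncols: int = 60
    cell_size_km: float = 1.0
    n_layers: int = 10
    autocorr_range_km: float = 8.0
    # virtual species
    n_species: int = 20
    n_occurrences: int = 200
    prevalence_range: tuple[float, float] = (0.05, 0.25)
    # future climate
    n_future_replicates: int = 5
    future_shift: float = 0.75
    future_noise_sd: float = 0.25
    # masks, costs, settlements
    pa_fraction: float = 0.10
    pa_patches: int = 5
    n_city: int = 3
    n_inst: int = 4
    # cleaning
    city_buffer_km: float = 10.0
    inst_buffer_km: float = 0.1
    min_records: int = 5
    # sdm
    vif_threshold: float = 10.0
    tss_min: float = 0.7
    algorithms: tuple[str, ...] = sdm.ALGORITHMS
    # prioritization
    blm: float = 0.001
    spf: float | None = None
    n_runs: int = 20
    n_iterations: int = 5000
    lockout_buffer_km: float = 5.0
    full_scale: bool = False
    run_local_moran: bool = True
    moran_permutations: int = 199

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineRun:
    """In-memory state shared across stages plus the final report."""

    config: RunConfig
    grid: GridSpec = None
    stack: EnvStack = None
    future_replicates: list = field(default_factory=list)
    future_mean: EnvStack = None
    species: list = field(default_factory=list)  # VirtualSpecies
    occurrences: pd.DataFrame = None
    settlements: synth.SettlementSet = None
    pa_mask: np.ndarray = None
    cost_surface: np.ndarray = None
    cleaned: pd.DataFrame = None
    cleaning_report: occ.CleaningReport = None
    selected_layers: list = field(default_factory=list)
    sdm_results: dict = field(default_factory=dict)
    ranges_current: list = field(default_factory=list)
    ranges_future: list = field(default_factory=list)
    unmodelled: list = field(default_factory=list)
    extinct: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    protection_records: list = field(default_factory=list)
    prioritization: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _stage_simulate(run: PipelineRun) -> None:
    cfg = run.config
    seed = stage_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(seed)
    run.grid = GridSpec(cfg.nrows, cfg.ncols, cfg.cell_size_km)
    run.stack = synth.generate_env_stack(
        run.grid, cfg.n_layers, cfg.autocorr_range_km, seed=int(rng.integers(2**31))
    )
    shift = {
        name: cfg.future_shift * float(rng.uniform(0.5, 1.5))
        for name in run.stack.layer_names
    }
    run.future_replicates, run.future_mean = synth.make_future_replicates(
        run.stack, cfg.n_future_replicates, shift, cfg.future_noise_sd,
        cfg.autocorr_range_km, seed=int(rng.integers(2**31)),
    )
    run.settlements = synth.generate_settlements(
        run.grid, cfg.n_city, cfg.n_inst, seed=int(rng.integers(2**31))
    )
    run.pa_mask = synth.generate_pa_mask(
        run.grid, cfg.pa_fraction, cfg.pa_patches, seed=int(rng.integers(2**31))
    )
    run.cost_surface = synth.generate_cost_surface(
        run.grid, run.settlements, seed=int(rng.integers(2**31))
    )
    names = run.stack.layer_names
    frames = []
    for i in range(cfg.n_species):
        for _ in range(20):  # retry degenerate draws
            k = int(rng.integers(2, min(5, len(names)) + 1))
            chosen = rng.choice(names, size=k, replace=False)
            coef = {"intercept": float(rng.normal(0, 0.5))}
            coef.update({n: float(rng.normal(0, 2.0)) for n in chosen})
            prevalence = float(rng.uniform(*cfg.prevalence_range))
            try:
                vs = synth.define_virtual_species(
                    run.stack, coef, prevalence, species_id=f"sp{i + 1:03d}",
                    future_stack=run.future_mean, no_dispersal=True,
                )
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw a non-degenerate species")
        run.species.append(vs)
        frames.append(
            synth.sample_occurrences(vs, cfg.n_occurrences,
                                     seed=int(rng.integers(2**31)))
        )
    run.occurrences = pd.concat(frames, ignore_index=True)


def _stage_prep(run: PipelineRun) -> None:
    cfg = run.config
    boundary = np.ones(run.grid.shape, dtype=bool)
    run.cleaned, run.cleaning_report = occ.clean_pipeline(
        run.occurrences, run.settlements, run.grid, boundary,
        cfg.city_buffer_km, cfg.inst_buffer_km, cfg.min_records,
    )


def _stage_sdm(run: PipelineRun) -> None:
    cfg = run.config
    seed = stage_seed(cfg.seed, "sdm")
    rng = np.random.default_rng(seed)
    run.selected_layers = sdm.vif_select(
        run.stack, threshold=cfg.vif_threshold,
        n_sample=min(2000, run.grid.n_cells), seed=int(rng.integers(2**31)),
    )
    stack = run.stack.select(run.selected_layers)
    future = run.future_mean.select(run.selected_layers)
    metrics_frames = []
    for species_id, group in run.cleaned.groupby("species"):
        if len(group) < cfg.min_records:
            continue
        model = sdm.EnsembleSDM.from_occurrences(
            group, stack, species_id=str(species_id),
            algorithms=cfg.algorithms, tss_min=cfg.tss_min,
        )
        results = model.fit(seed=int(rng.integers(2**31)))
        run.sdm_results[species_id] = results
        metrics_frames.append(results.metrics_frame())
        if results.is_unmodelled:
            logger.warning("species %s unmodelled (no fit retained)", species_id)
            run.unmodelled.append(str(species_id))
            continue
        current = results.binarize(scenario="current")
        fut = results.project_future(future, no_dispersal=True, current=current)
        run.ranges_current.append(current)
        run.ranges_future.append(fut)
        if fut.is_empty:
            logger.warning("species %s: local extinction projected", species_id)
            run.extinct.append(str(species_id))
    run.metrics["sdm_table"] = (
        pd.concat(metrics_frames, ignore_index=True)
        if metrics_frames else pd.DataFrame()
    )


def _stage_metrics(run: PipelineRun) -> None:
    if not run.ranges_current:
        raise RuntimeError("no modelled species; cannot compute diversity maps")
    rich_cur = diversity.richness(run.ranges_current)
    rwr_cur = diversity.rwr(run.ranges_current)
    run.metrics["richness_current"] = rich_cur
    run.metrics["rwr_current"] = rwr_cur
    surviving = [r for r in run.ranges_future if not r.is_empty]
    if surviving:
        rich_fut = diversity.richness(surviving)
        rwr_fut = diversity.rwr(surviving)
        run.metrics["richness_future"] = rich_fut
        run.metrics["rwr_future"] = rwr_fut
        run.metrics["richness_change"] = diversity.richness_change(rich_cur, rich_fut)
        try:
            run.metrics["richness_rwr_r"] = diversity.pearson_map_correlation(
                rich_cur.values, rwr_cur.values
            )
        except ValueError:
            run.metrics["richness_rwr_r"] = np.nan
        try:
            z, p = diversity.wilcoxon_paired(
                rwr_cur.values.ravel(), rwr_fut.values.ravel()
            )
            run.metrics["rwr_wilcoxon"] = {"Z": z, "p": p}
        except ValueError:
            run.metrics["rwr_wilcoxon"] = {"Z": np.nan, "p": np.nan}


def _stage_gap(run: PipelineRun) -> None:
    records = []
    for r in run.ranges_current:
        records.append(gap.protection_record(r, run.pa_mask))
    for r in run.ranges_future:
        if not r.is_empty:
            records.append(gap.protection_record(r, run.pa_mask))
    run.protection_records = records
    run.metrics["gap_summary"] = gap.summarize(records)
    run.metrics["fully_outside"] = gap.count_fully_outside(
        [r for r in records if r.scenario == "current"]
    )


def _stage_prioritize(run: PipelineRun) -> None:
    cfg = run.config
    seed = stage_seed(cfg.seed, "prioritize")
    params = prioritize.SAParams(
        blm=cfg.blm, spf=cfg.spf, n_iterations=cfg.n_iterations,
        n_runs=cfg.n_runs, full_scale=cfg.full_scale,
    )
    scenarios = {
        "current": run.ranges_current,
        "future": [r for r in run.ranges_future if not r.is_empty],
    }
    for scen, ranges in scenarios.items():
        if not ranges:
            continue
        problem = prioritize.build_problem(
            ranges, run.pa_mask, run.cost_surface, run.settlements,
            run.grid, buffer_km=cfg.lockout_buffer_km,
        )
        results = prioritize.run_portfolio(
            problem, params, seed=stage_seed(seed, scen)
        )
        entry = {"problem": problem, "results": results}
        if cfg.run_local_moran:
            entry["moran"] = prioritize.local_morans_i(
                results.selection_frequency_map(),
                n_permutations=cfg.moran_permutations,
                seed=stage_seed(seed, f"moran_{scen}"),
            )
        run.prioritization[scen] = entry
    if {"current", "future"} <= run.prioritization.keys():
        labels, summary = prioritize.overlap_cpas(
            run.prioritization["current"]["results"].best_map(),
            run.prioritization["future"]["results"].best_map(),
            run.grid,
        )
        run.prioritization["overlap"] = {"labels": labels, "summary": summary}


def _stage_report(run: PipelineRun) -> None:
    cfg = run.config
    pa_fraction = float(run.pa_mask.mean())
    report: dict = {
        "config_hash": run.config.config_hash(),
        "seed": cfg.seed,
        "grid": {"nrows": cfg.nrows, "ncols": cfg.ncols},
        "n_species_simulated": len(run.species),
        "n_species_modelled": len(run.ranges_current),
        "unmodelled_species": run.unmodelled,
        "local_extinctions": run.extinct,
        "n_local_extinctions": len(run.extinct),
        "pa_coverage_fraction": pa_fraction,
        "fully_outside_current": run.metrics.get("fully_outside"),
    }
    if "richness_rwr_r" in run.metrics:
        report["richness_rwr_pearson_r"] = run.metrics["richness_rwr_r"]
    if "rwr_wilcoxon" in run.metrics:
        report["rwr_wilcoxon"] = run.metrics["rwr_wilcoxon"]
    for scen in ("current", "future"):
        entry = run.prioritization.get(scen)
        if entry:
            report[f"cpa_coverage_fraction_{scen}"] = entry["results"].cpa_fraction
            report[f"targets_met_{scen}"] = int(entry["results"].best.feasible.sum())
            report[f"n_features_{scen}"] = entry["problem"].n_features
    if "overlap" in run.prioritization:
        report["cpa_overlap"] = run.prioritization["overlap"]["summary"].to_dict(
            orient="records"
        )
    run.report = report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "sdm": _stage_sdm,
    "metrics": _stage_metrics,
    "gap": _stage_gap,
    "prioritize": _stage_prioritize,
    "report": _stage_report,
}


def run_pipeline(
    config: RunConfig,
    upto: str = "report",
    write_outputs: bool = True,
) -> PipelineRun:
    """Execute the stages in order up to ``upto``; optionally write outputs."""
    if upto not in _STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {_STAGES}")
    run = PipelineRun(config=config)
    for stage in _STAGES[: _STAGES.index(upto) + 1]:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    if write_outputs:
        _write_outputs(run, upto)
    return run


def _write_outputs(run: PipelineRun, upto: str) -> None:
    cfg = run.config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(cfg), "config_hash": cfg.config_hash()},
            fh, indent=2, default=str,
        )
    done = _STAGES[: _STAGES.index(upto) + 1]
    if "simulate" in done:
        run.stack.write(outdir / "layers_current")
        run.future_mean.write(outdir / "layers_future_mean")
        run.occurrences.to_csv(outdir / "occurrences_raw.csv", index=False)
        run.settlements.points.to_csv(outdir / "settlements.csv", index=False)
        write_ascii_grid(outdir / "pa_mask.asc", run.pa_mask.astype(float), run.grid)
        write_ascii_grid(outdir / "cost_surface.asc", run.cost_surface, run.grid)
    if "prep" in done:
        run.cleaned.to_csv(outdir / "occurrences_clean.csv", index=False)
        run.cleaning_report.to_frame().to_csv(
            outdir / "cleaning_report.csv", index=False
        )
    if "sdm" in done and len(run.metrics.get("sdm_table", [])):
        run.metrics["sdm_table"].to_csv(outdir / "sdm_metrics.csv", index=False)
        pd.DataFrame(
            [
                {"species": c.species_id, "scenario": c.scenario, "c": c.c,
                 "area_km2": c.area_km2}
                for c in run.ranges_current + run.ranges_future
            ]
        ).to_csv(outdir / "range_sizes.csv", index=False)
    if "metrics" in done and "richness_current" in run.metrics:
        for key in ("richness_current", "richness_future",
                    "rwr_current", "rwr_future"):
            m = run.metrics.get(key)
            if m is not None:
                write_ascii_grid(outdir / f"{key}.asc",
                                 np.asarray(m.values, dtype=float), run.grid)
    if "gap" in done and "gap_summary" in run.metrics:
        run.metrics["gap_summary"].to_csv(outdir / "gap_summary.csv", index=False)
    if "prioritize" in done:
        for scen in ("current", "future"):
            entry = run.prioritization.get(scen)
            if entry:
                write_ascii_grid(
                    outdir / f"selection_frequency_{scen}.asc",
                    entry["results"].selection_frequency_map(), run.grid,
                )
                write_ascii_grid(
                    outdir / f"best_solution_{scen}.asc",
                    entry["results"].best_map().astype(float), run.grid,
                )
        if "overlap" in run.prioritization:
            run.prioritization["overlap"]["summary"].to_csv(
                outdir / "cpa_overlap.csv", index=False
            )
    if "report" in done:
        with open(outdir / "report.json", "w") as fh:
            json.dump(run.report, fh, indent=2, default=float)
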