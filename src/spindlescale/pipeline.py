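"""Configured end-to-end runs: generate -> analyze -> fit -> report.

A :class:`RunConfig` fixes the global seed, the participating states with
their sample sizes, the cell-volume bin edges, track filter rules and model
constants. :func:`run_pipeline` executes the stages in order — synthetic
generation (or CSV ingestion), scaling statistics, FRAP fitting, comet
analytics, densitometry, model fitting — writes every intermediate table
under the output directory and returns a machine-readable report. Identical
config + seed produces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cpapmodel, densito, eb1, frap, io, scaling, synthgen
from .errors import SpindleScaleError, ValidationError
from .params import StateParams, split_seed, state_defaults
from .scaling import DEFAULT_BIN_EDGES

__version__ = "0.1.0"

log = logging.getLogger("spindlescale")


@dataclass
class StageConfig:
    """Per-stage sample sizes; a stage with zero entries is skipped."""

    population_n: dict[str, int] = field(
        default_factory=lambda: {"ESC": 1084, "DIF": 2920})
    frap_n: dict[str, int] = field(
        default_factory=lambda: {"ESC": 31, "DIF": 31})
    comet_cells: dict[str, int] = field(
        default_factory=lambda: {"ESC": 92, "DIF": 75})
    tracks_per_cell: int = 60
    profiles_n: dict[str, int] = field(
        default_factory=lambda: {"ESC": 158, "DIF": 98})
    density_n: dict[str, int] = field(
        default_factory=lambda: {"ESC": 60, "DIF": 70, "ISO": 107, "HYPO": 96})
    blot_true_percent: float = 1.5
    blot_noise_cv: float = 0.05
    model_n: dict[str, int] = field(
        default_factory=lambda: {"ESC": 2000, "DIF": 2000})


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    global_seed: int = 1
    output_dir: str = "spindlescale_run"
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    ri_medium: float = 1.337
    state_overrides: dict[str, dict] = field(default_factory=dict)
    filter_rules: eb1.TrackFilterRules = field(default_factory=eb1.TrackFilterRules)
    stages: StageConfig = field(default_factory=StageConfig)
    log_level: str = "INFO"

    def state(self, label: str) -> StateParams:
        base = state_defaults(label)
        overrides = self.state_overrides.get(label, {})
        return base.with_overrides(**overrides) if overrides else base

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bin_edges"] = list(self.bin_edges)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs go and how
        verbosely the run logs do not change the science)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("global_seed", "output_dir", "ri_medium", "log_level"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "bin_edges" in raw:
            cfg.bin_edges = tuple(float(e) for e in raw["bin_edges"])
        if "state_overrides" in raw:
            cfg.state_overrides = {
                k: dict(v) for k, v in raw["state_overrides"].items()
            }
        if "filter_rules" in raw:
            fr = raw["filter_rules"]
            cfg.filter_rules = eb1.TrackFilterRules(
                min_duration=fr.get("min_duration", 2.0),
                max_duration=fr.get("max_duration", 4.0),
                quality_range=tuple(fr.get("quality_range", (200.0, 600.0))),
                start_end_window=tuple(fr.get("start_end_window", (0, 30))),
            )
        if "stages" in raw:
            st = raw["stages"]
            defaults = StageConfig()
            for fname in vars(defaults):
                if fname in st:
                    setattr(defaults, fname, st[fname])
            cfg.stages = defaults
        return cfg


def ingest_records(path) -> list:
    """Load and validate user-supplied cell records from CSV.

    Thin wrapper over :func:`spindlescale.io.read_cell_records`: header must
    match the documented schema (units in column names); invariant
    violations are reported per row with CSV line numbers.
    """
    return io.read_cell_records(path)


def _stage_seed(cfg: RunConfig, *keys: str) -> int:
    return split_seed(cfg.global_seed, *keys)


def run_pipeline(config: RunConfig, records_csv: str | None = None) -> dict:
    """Execute all configured stages and return the run report.

    With ``records_csv``, the morphometric population is ingested from the
    given CSV instead of being generated (the CSV must carry the documented
    schema); all other stages still run on synthetic inputs. Any stage
    failure aborts with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": 1,
        "provenance": {
            "seed": config.global_seed,
            "config_hash": config.config_hash(),
            "package_version": __version__,
        },
    }
    stage = "simulate"
    try:
        populations = _stage_simulate(config, out, records_csv, report)
        stage = "scaling"
        _stage_scaling(config, populations, report)
        stage = "frap"
        _stage_frap(config, out, report)
        stage = "eb1"
        _stage_eb1(config, out, report)
        stage = "density"
        _stage_density(config, out, report)
        stage = "model"
        _stage_model(config, out, report)
    except SpindleScaleError as exc:
        raise SpindleScaleError(f"stage '{stage}' failed: {exc}") from exc
    io.write_json_report(report, out / "report.json")
    return report


def _stage_simulate(config, out, records_csv, report):
    populations: dict[str, list] = {}
    if records_csv is not None:
        records = ingest_records(records_csv)
        for rec in records:
            populations.setdefault(rec.state_label, []).append(rec)
        log.info("simulate: ingested %d records from %s", len(records), records_csv)
    else:
        for label, n in config.stages.population_n.items():
            if n <= 0:
                continue
            params = config.state(label)
            seed = _stage_seed(config, "population", label)
            populations[label] = synthgen.generate_cell_population(params, n, seed)
            log.info("simulate[%s]: n=%d seed=%d", label, n, seed)
    for label, recs in populations.items():
        io.write_cell_records(recs, out / f"cells_{label}.csv")
    report["populations"] = {
        label: {
            "n": len(recs),
            "mean_V_cell_um3": float(np.mean([r.V_cell for r in recs])),
            "mean_rho_mg_per_ml": float(np.mean([r.mass_density for r in recs])),
        }
        for label, recs in populations.items()
    }
    return populations


def _stage_scaling(config, populations, report):
    if not populations:
        return
    block: dict = {}
    pooled_V, pooled_S = [], []
    for recs in populations.values():
        pooled_V += [r.V_cell for r in recs]
        pooled_S += [r.V_spindle for r in recs]
    if len(pooled_V) >= 3:
        block["spearman_V_spindle_vs_V_cell"] = scaling.spearman_rho(
            pooled_V, pooled_S)

    if "ESC" in populations and "DIF" in populations:
        esc, dif = populations["ESC"], populations["DIF"]
        bins_esc = scaling.summarize_bins(
            scaling.bin_by_cell_volume(esc, config.bin_edges))
        bins_dif = scaling.summarize_bins(
            scaling.bin_by_cell_volume(dif, config.bin_edges))
        profile = scaling.subscaling_profile(bins_esc, bins_dif)
        block["subscaling"] = {
            "bin_lows_um3": list(profile.bin_lows),
            "deficits_percent": [None if np.isnan(d) else d
                                 for d in profile.deficits_percent],
            "max_deficit_percent": profile.max_deficit_percent,
        }
        cmp_v = scaling.compare_groups([r.V_cell for r in esc],
                                       [r.V_cell for r in dif])
        block["cell_volume_comparison"] = {
            "t": cmp_v.t_statistic, "p": cmp_v.p_two_sided,
            "cohens_d": cmp_v.cohens_d,
        }
        occ_esc = [scaling.occupancy(r.V_centrosome, r.V_cell) for r in esc]
        occ_dif = [scaling.occupancy(r.V_centrosome, r.V_cell) for r in dif]
        fold = scaling.fold_change_vs_control(occ_dif, occ_esc)
        block["centrosome_occupancy_fold_DIF_vs_ESC"] = fold.median_fold
    report["scaling"] = block


def _stage_frap(config, out, report):
    block = {}
    for label, n in config.stages.frap_n.items():
        if n <= 0:
            continue
        params = config.state(label)
        seed = _stage_seed(config, "frap", label)
        traces = synthgen.generate_frap_traces(params, n, seed)
        io.write_frap_traces(traces, out / f"frap_{label}.csv")
        mean_th, sd_th, _ = frap.mean_half_time(traces)
        block[label] = {"mean_t_half_s": mean_th, "sd_t_half_s": sd_th, "n": n}
        log.info("frap[%s]: t_half = %.2f +/- %.2f s", label, mean_th, sd_th)
    if block:
        report["frap"] = block


def _stage_eb1(config, out, report):
    block = {}
    for label, n_cells in config.stages.comet_cells.items():
        if n_cells <= 0:
            continue
        params = config.state(label)
        seed = _stage_seed(config, "eb1", label)
        tracks = synthgen.generate_comet_tracks(
            params, n_cells, config.stages.tracks_per_cell, seed)
        io.write_comet_tracks(tracks, out / f"eb1_tracks_{label}.csv")
        kept, rejected = eb1.filter_tracks(tracks, config.filter_rules)
        speeds = eb1.per_cell_speeds(kept)
        block[label] = {
            "n_cells": n_cells,
            "n_tracks_kept": len(kept),
            "n_tracks_rejected": len(rejected),
            "grand_mean_speed_um_per_s": float(np.mean(list(speeds.values()))),
        }
    for label, n_prof in config.stages.profiles_n.items():
        if n_prof <= 0:
            continue
        params = config.state(label)
        seed = _stage_seed(config, "profiles", label)
        profiles = synthgen.generate_half_spindle_profiles(params, n_prof, seed)
        io.write_profiles(profiles, out / f"profiles_{label}.csv")
        fractions = [eb1.pole_signal_fraction(p) for p in profiles]
        block.setdefault(label, {})["mean_pole_signal_percent"] = float(
            np.mean(fractions))
    if block:
        report["eb1"] = block


def _stage_density(config, out, report):
    if not config.stages.density_n:
        return
    block = {}
    for label, n in config.stages.density_n.items():
        if n <= 0:
            continue
        params = config.state(label)
        seed = _stage_seed(config, "density", label)
        measurements = synthgen.generate_ri_measurements(
            params, n, seed, ri_medium=config.ri_medium)
        io.write_ri_measurements(measurements, out / f"ri_{label}.csv")
        rho = densito.densities_from_measurements(measurements)
        block[label] = {"n": n, "mean_rho_mg_per_ml": float(rho.mean()),
                        "sd_rho_mg_per_ml": float(rho.std(ddof=1))}
    if "ISO" in block and "HYPO" in block:
        block["density_fold_HYPO_vs_ISO"] = (
            block["HYPO"]["mean_rho_mg_per_ml"] / block["ISO"]["mean_rho_mg_per_ml"])
    blot = synthgen.generate_blot_dataset(
        config.stages.blot_true_percent,
        noise_cv=config.stages.blot_noise_cv,
        seed=_stage_seed(config, "blot"),
    )
    io.write_blot(blot, out / "blot_standards.csv", out / "blot_lanes.csv")
    quant = densito.quantify_tubulin_fraction(blot)
    block["tubulin_fraction_percent"] = quant.fraction_percent
    report["density"] = block


def _stage_model(config, out, report):
    block = {}
    for label, n in config.stages.model_n.items():
        if n <= 0:
            continue
        params = config.state(label)
        model = cpapmodel.model_params_for_state(params)
        seed = _stage_seed(config, "model", label)
        records = synthgen.generate_cell_population(params, n, seed, model=model)
        fit, summary = cpapmodel.fit_state_counts(
            records, model, cpapmodel.MODEL_BIN_EDGES, use_true_counts=True)
        block[label] = {
            "N_sat": fit.N_sat,
            "K_V_um3": fit.K_V,
            "residual_rms": fit.residual_rms,
            "identifiable": fit.identifiable,
            "bins": summary,
        }
    if block:
        report["model"] = block
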