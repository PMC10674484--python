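"""Pipeline orchestration: validated config, staged execution, JSON reports.

A run is described by a small mapping (usually loaded from YAML): a seed,
an output directory and a list of stages.  Each stage writes one JSON
report into the output directory; the hydro and structmetrics stages
additionally emit delimited summary tables laid out like the
concentration series (concentration, <tau>, r, Vh, Rh) and the species
series (label, Rg, Vg, Rh, Vh) of an aggregation study.  Reports carry
no timestamps, so identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import json
import logging
from importlib import metadata as importlib_metadata
from pathlib import Path
from typing import Any, Dict, List

import numpy as np
import pandas as pd

from . import cac as cac_mod
from . import decay as decay_mod
from . import hydrodynamics as hydro_mod
from . import structure as struct_mod
from . import synthetic

logger = logging.getLogger("lipoagg")

STAGES = ("simulate", "fit_decay", "hydro", "cac", "structmetrics")

#: Published schema for RunConfig: key -> (type, required).
CONFIG_SCHEMA: Dict[str, Any] = {
    "seed": (int, True),
    "output_dir": (str, True),
    "stages": (list, True),
    "simulate": (dict, False),
    "fit_decay": (dict, False),
    "hydro": (dict, False),
    "cac": (dict, False),
    "structmetrics": (dict, False),
}

__all__ = ["ConfigError", "StageError", "validate_config", "run_pipeline",
           "CONFIG_SCHEMA", "STAGES"]


class ConfigError(ValueError):
    """A RunConfig violates the published schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def _package_version() -> str:
    try:
        return importlib_metadata.version("lipoagg")
    except importlib_metadata.PackageNotFoundError:
        return "unknown"


def validate_config(config: Dict[str, Any]) -> Dict[str, Any]:
    """Check a config mapping against :data:`CONFIG_SCHEMA`.

    Raises :class:`ConfigError` naming the offending field; returns the
    config unchanged when valid.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key in config:
        if key not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown config field: {key!r}")
    for key, (typ, required) in CONFIG_SCHEMA.items():
        if key in config and not isinstance(config[key], typ):
            raise ConfigError(f"field {key!r} must be of type {typ.__name__}")
        if required and key not in config:
            raise ConfigError(f"missing required config field: {key!r}")
    stages = config["stages"]
    if len(stages) == 0:
        raise ConfigError("field 'stages' must name at least one stage")
    for stage in stages:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}; valid: {STAGES}")
    for stage, options in config.items():
        if stage in STAGES and isinstance(options, dict):
            for key in ("trace", "table", "pdb", "spectra_dir"):
                path = options.get(key)
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"field {stage}.{key}: path {path!r} "
                                      "does not exist")
    return config


def _write_report(out_dir: Path, name: str, payload: Dict[str, Any]) -> None:
    (out_dir / f"{name}.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: Dict[str, Any]) -> Dict[str, Any]:
    """Execute the stages named in ``config`` and write their reports.

    Returns the combined report mapping (also written as summary.json).
    Stage failures raise :class:`StageError` carrying the stage name.
    """
    validate_config(config)
    seed = config["seed"]
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: Dict[str, Any] = {
        "seed": seed,
        "package_version": _package_version(),
        "stages": list(config["stages"]),
    }
    logger.info("run: seed=%d version=%s stages=%s",
                seed, reports["package_version"], config["stages"])
    context: Dict[str, Any] = {}
    for stage in config["stages"]:
        options = config.get(stage, {}) or {}
        runner = _STAGE_RUNNERS[stage]
        try:
            reports[stage] = runner(options, seed, out_dir, context)
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    _write_report(out_dir, "summary", reports)
    return reports


# ---------------------------------------------------------------------------
# stage runners: (options, seed, out_dir, context) -> report dict

def _run_simulate(options, seed, out_dir, context):
    decay_opts = dict(options.get("decay", {}))
    decay_opts.setdefault("seed", seed)
    decay_spec = synthetic.DecaySimSpec(**decay_opts)
    trace = synthetic.generate_decay(decay_spec)
    trace_path = out_dir / "synthetic_decay.tsv"
    decay_mod.write_decay_table(trace, trace_path)
    context["trace"] = trace

    titr_opts = dict(options.get("titration", {}))
    titr_opts.setdefault("seed", seed + 1)
    titr_opts.setdefault("noise_sd", 0.02)
    titr_spec = synthetic.TitrationSimSpec(**titr_opts)
    series = synthetic.generate_titration(titr_spec)
    titr_path = out_dir / "synthetic_titration.tsv"
    np.savetxt(titr_path,
               np.column_stack([series.concentrations_uM, series.ratios]),
               header="concentration_uM\tratio", fmt="%.8g", delimiter="\t")
    context["titration"] = series

    helix = synthetic.build_helix(int(options.get("helix_residues", 32)))
    pdb_path = out_dir / "synthetic_helix.pdb"
    synthetic.write_geometry_pdb(helix, pdb_path)
    context["pdb"] = pdb_path
    logger.info("simulate: decay peak=%g, titration breakpoint=%g uM",
                decay_spec.peak_counts, titr_spec.breakpoint_uM)
    return {
        "decay_trace": str(trace_path),
        "decay_components_true": list(decay_spec.components),
        "titration_table": str(titr_path),
        "titration_breakpoint_true_uM": titr_spec.breakpoint_uM,
        "helix_pdb": str(pdb_path),
        "seed": seed,
    }


def _run_fit_decay(options, seed, out_dir, context):
    if "trace" in options:
        trace = decay_mod.read_decay_table(options["trace"])
    elif "trace" in context:
        trace = context["trace"]
    else:
        raise ConfigError("fit_decay.trace: no trace given and none simulated")
    fit = decay_mod.fit_multiexponential(
        trace,
        n_components=int(options.get("n_components", 3)),
        fit_start=options.get("fit_start"),
        reconvolve=bool(options.get("reconvolve", False)),
    )
    decay_mod.write_fit_report(fit, out_dir / "decay_fit.json",
                               out_dir / "decay_fit_curve.tsv")
    context["average_lifetime_ns"] = fit.average_lifetime_ns
    logger.info("fit_decay: <tau>=%.3f ns chi2r=%.3f flag=%s",
                fit.average_lifetime_ns, fit.chi2_reduced, fit.flag)
    return {
        "components": [{"alpha": a, "tau_ns": t} for a, t in fit.components],
        "average_lifetime_ns": fit.average_lifetime_ns,
        "chi2_reduced": fit.chi2_reduced,
        "flag": fit.flag,
    }


def _hydro_conditions(options) -> hydro_mod.HydroConditions:
    cond = options.get("conditions", {}) or {}
    return hydro_mod.HydroConditions(
        viscosity_cP=float(cond.get("viscosity_cP", 0.89)),
        temperature_K=float(cond.get("temperature_K", 298.0)),
        r0=float(cond.get("r0", 0.260)),
    )


def _run_hydro(options, seed, out_dir, context):
    cond = _hydro_conditions(options)
    if "table" in options:
        table = pd.read_csv(options["table"], sep=None, engine="python",
                            comment="#")
    elif "rows" in options:
        table = pd.DataFrame(options["rows"])
    else:
        raise ConfigError("hydro.table: a table path or inline rows required")
    out = hydro_mod.hydro_table(table, cond)
    table_path = out_dir / "hydro_table.tsv"
    out.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
    logger.info("hydro: %d rows, r0=%.3f eta=%.3g cP T=%.1f K",
                len(out), cond.r0, cond.viscosity_cP, cond.temperature_K)
    return {
        "conditions": {"viscosity_cP": cond.viscosity_cP,
                       "temperature_K": cond.temperature_K, "r0": cond.r0},
        "table": str(table_path),
        "rows": out.to_dict(orient="records"),
    }


def _run_cac(options, seed, out_dir, context):
    if "table" in options:
        series = cac_mod.read_ratio_table(options["table"])
    elif "spectra_dir" in options:
        series = cac_mod.read_spectra_dir(options["spectra_dir"])
    elif "titration" in context:
        series = context["titration"]
    else:
        raise ConfigError("cac.table: no titration given and none simulated")
    fit = cac_mod.fit_cac_segmented(
        series,
        method=options.get("method", "grid_breakpoint"),
        n_bootstrap=int(options.get("n_bootstrap", 500)),
        seed=seed,
    )
    cac_mod.write_cac_report(fit, series, out_dir / "cac_fit.json",
                             out_dir / "cac_segments.tsv")
    logger.info("cac: flag=%s cac=%s uM", fit.flag, fit.cac_uM)
    return {
        "cac_uM": fit.cac_uM,
        "log10_cac": fit.log10_cac,
        "bootstrap_ci_uM": fit.bootstrap_ci_uM,
        "flag": fit.flag,
        "n_points": len(series),
    }


def _run_structmetrics(options, seed, out_dir, context):
    if "pdb" in options:
        pdb_path = options["pdb"]
    elif "pdb" in context:
        pdb_path = context["pdb"]
    else:
        raise ConfigError("structmetrics.pdb: no structure given and none simulated")
    traj = struct_mod.read_structure(pdb_path)
    metrics = struct_mod.trajectory_summary(
        traj,
        rh_selection=options.get("rh_selection", "C"),
        rmsf_selection=options.get("rmsf_selection", "CA"),
    )
    struct_mod.write_metrics_report(
        metrics, out_dir / "struct_metrics.json",
        out_dir / "struct_per_frame.tsv",
        out_dir / "struct_rmsf.tsv" if metrics.rmsf_A is not None else None,
    )
    label = options.get("label", Path(str(pdb_path)).stem)
    species_table = pd.DataFrame([{
        "species": label,
        "Rg_A": metrics.rg_mean_A, "Vg_nm3": metrics.Vg_nm3,
        "Rh_A": metrics.rh_mean_A, "Vh_nm3": metrics.Vh_nm3,
    }])
    species_path = out_dir / "species_table.tsv"
    species_table.to_csv(species_path, sep="\t", index=False,
                         float_format="%.6g")
    logger.info("structmetrics: %s Rg=%.2f A Rh=%.2f A",
                label, metrics.rg_mean_A, metrics.rh_mean_A)
    report = metrics.to_dict()
    report["species"] = label
    report["table"] = str(species_path)
    return report


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "fit_decay": _run_fit_decay,
    "hydro": _run_hydro,
    "cac": _run_cac,
    "structmetrics": _run_structmetrics,
}
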