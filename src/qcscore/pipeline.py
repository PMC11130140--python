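"""End-to-end pipeline orchestration driven by one YAML config.

Stages: simulate -> features -> consolidate -> stratify -> crossval.  Each
stage writes its outputs into the run directory and the run closes with a
versioned JSON manifest (config hash, seeds, per-stage artifacts,
warnings).  Re-running with an identical config reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SimulationConfig, simulate_cohort
from .consolidate import consolidate
from .crossval import CrossValConfig, permutation_pvalue
from .cutpoint import bootstrap_cutpoint, stratify
from .features import FeatureGrid, compute_readout_matrix, expand_feature_grid
from .tables import frames_to_samples, read_clinical, write_cohort, _read_table, _write_table

log = logging.getLogger("qcscore")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


DEFAULT_STAGES = ("simulate", "features", "consolidate", "stratify", "crossval")


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(DEFAULT_STAGES))
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": _jsonable(config),
        "stages": {},
        "warnings": [],
    }
    state: dict[str, Any] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in stages:
            runner = _STAGE_RUNNERS.get(stage)
            if runner is None:
                raise PipelineError(f"stage {stage!r}: unknown stage")
            log.info("running stage %s", stage)
            try:
                manifest["stages"][stage] = runner(config.get(stage, {}) or {}, outdir, state)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort naming the stage
                _write_manifest(manifest, outdir)
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["warnings"] = [str(w.message) for w in caught]
    _write_manifest(manifest, outdir)
    return outdir


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)


def _stage_simulate(cfg: dict, outdir: Path, state: dict) -> dict:
    cfg = dict(cfg)
    planted = cfg.pop("planted_feature", None)
    sim_cfg = SimulationConfig(**cfg)
    if planted is not None:
        from .features import FeatureSpec

        sim_cfg = dataclasses.replace(sim_cfg, planted_feature=FeatureSpec(**planted))
    samples, clinical = simulate_cohort(sim_cfg)
    paths = write_cohort(samples, clinical, outdir / "cohort")
    state["samples"], state["clinical"] = samples, clinical
    return {"outputs": paths, "seed": sim_cfg.seed, "n_patients": sim_cfg.n_patients}


def _load_samples(cfg: dict, state: dict) -> None:
    if "samples" in state:
        return
    cells = _read_table(cfg["cells"])
    tils = _read_table(cfg["tils"]) if cfg.get("tils") else None
    areas = _read_table(cfg["areas"]) if cfg.get("areas") else None
    state["samples"] = frames_to_samples(cells, tils, areas)


def _stage_features(cfg: dict, outdir: Path, state: dict) -> dict:
    _load_samples(cfg, state)
    grid_cfg = cfg.get("grid", {})
    grid = FeatureGrid(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in grid_cfg.items()
        }
    )
    specs = expand_feature_grid(grid)
    matrix = compute_readout_matrix(state["samples"], specs)
    out = outdir / "readouts.parquet"
    _write_table(matrix.values.reset_index(), out)
    sidecar = outdir / "readouts.specs.json"
    with open(sidecar, "w") as fh:
        json.dump([_jsonable(s) for s in specs], fh, indent=2)
    state["readouts"] = matrix.values
    return {
        "outputs": {"readouts": str(out), "specs": str(sidecar)},
        "n_readouts": len(specs),
        "failures": matrix.failures,
    }


def _stage_consolidate(cfg: dict, outdir: Path, state: dict) -> dict:
    if "readouts" not in state:
        state["readouts"] = _read_table(cfg["readouts"]).set_index("patient_id")
    rho = float(cfg.get("rho", 0.99))
    reduced, report = consolidate(state["readouts"], rho=rho, return_report=True)
    out = outdir / "readouts_unique.parquet"
    _write_table(reduced.reset_index(), out)
    report_path = outdir / "consolidation.json"
    with open(report_path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    state["readouts_unique"] = reduced
    return {
        "outputs": {"readouts_unique": str(out), "report": str(report_path)},
        "n_before": state["readouts"].shape[1],
        "n_after": reduced.shape[1],
    }


def _aligned_readout(cfg: dict, state: dict) -> tuple[np.ndarray, pd.DataFrame, str]:
    if "clinical" not in state:
        state["clinical"] = read_clinical(cfg["clinical"])
    clinical = state["clinical"]
    readouts = state.get("readouts_unique", state.get("readouts"))
    if readouts is None:
        readouts = _read_table(cfg["readouts"]).set_index("patient_id")
    name = cfg.get("readout")
    if name is None:
        raise ValueError("a 'readout' name must be configured")
    aligned = readouts.loc[clinical["patient_id"].astype(str).tolist(), name]
    return aligned.to_numpy(float), clinical, name


def _stage_stratify(cfg: dict, outdir: Path, state: dict) -> dict:
    values, clinical, name = _aligned_readout(cfg, state)
    cut = bootstrap_cutpoint(
        values,
        clinical,
        target=cfg.get("target", "logrank"),
        n_bootstrap=int(cfg.get("bootstrap", 50)),
        min_prevalence=float(cfg.get("min_prevalence", 0.2)),
        seed=int(cfg.get("seed", 0)),
    )
    result = stratify(values, cut, clinical, readout=name)
    out = outdir / "stratification.json"
    payload = _jsonable(result)
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2)
    outputs = {"stratification": str(out)}
    for arm in ("high", "low"):
        km = getattr(result, arm).km
        if km is not None:
            km_path = outdir / f"km_{arm}.csv"
            pd.DataFrame({"time_months": km.timeline, "survival": km.survival}).to_csv(
                km_path, index=False
            )
            outputs[f"km_{arm}"] = str(km_path)
    state["cut"] = cut
    return {"outputs": outputs, "cut": cut, "readout": name}


def _stage_crossval(cfg: dict, outdir: Path, state: dict) -> dict:
    values, clinical, name = _aligned_readout(cfg, state)
    cv_cfg = CrossValConfig(
        k=int(cfg.get("k", 5)),
        n_repeats=int(cfg.get("n", 300)),
        m_permutations=int(cfg.get("m", 1200)),
        n_bootstrap=int(cfg.get("bootstrap", 50)),
        target=cfg.get("target", "logrank"),
        min_prevalence=float(cfg.get("min_prevalence", 0.2)),
        perm_repeats=cfg.get("perm_repeats"),
        seed=int(cfg.get("seed", 0)),
    )
    result = permutation_pvalue(values, clinical, cv_cfg)
    cv = result.cross_validation
    out = outdir / "crossval.json"
    payload = {
        "readout": name,
        "empirical_p": result.p_value,
        "observed_statistic": result.observed_statistic,
        "mean_statistic": cv.statistic,
        "prevalence_mean_pct": cv.prevalence_mean_pct,
        "prevalence_sd_pct": cv.prevalence_sd_pct,
        "orr_high_mean_pct": cv.orr_high_mean_pct,
        "orr_low_mean_pct": cv.orr_low_mean_pct,
        "n_failed_splits": cv.n_failed_splits,
        "null_statistics": result.null_statistics,
    }
    with open(out, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2)
    return {"outputs": {"crossval": str(out)}, "empirical_p": result.p_value}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "consolidate": _stage_consolidate,
    "stratify": _stage_stratify,
    "crossval": _stage_crossval,
}
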