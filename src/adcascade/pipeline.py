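"""End-to-end orchestration: simulate -> preprocess -> compare ->
trajectory -> mediate, with a machine-readable run manifest.

Every random stage carries an explicit seed recorded in the manifest,
and all JSON output is written with sorted keys and no timestamps, so
the same config produces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .demographics import compare_demographics, demographics_table
from .group_compare import compare_by_pathology_group
from .mediation import MediationSpec, bootstrap_mediation
from .preprocess import DEFAULT_AAO, build_analysis_table
from .synthetic_cohort import (
    CohortConfig,
    default_config,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .trajectory import compare_divergence_timing, estimate_divergence_age

logger = logging.getLogger("adcascade")

BIOMARKER_STAGE_DEFAULTS = ("centiloid", "ptau217", "gfap", "tau_suvr")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str
    cohort_csv: str | None = None  # external cohort; otherwise synthetic
    synthetic: CohortConfig | None = None
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "preprocess": True,
            "compare": True,
            "trajectory": True,
            "mediate": True,
        }
    )
    aao: float = DEFAULT_AAO
    centiloid_threshold: float = 18.0
    tau_threshold: float = 1.3
    compare_biomarkers: tuple[str, ...] = ("gfap", "ptau217")
    trajectory_biomarkers: tuple[str, ...] = BIOMARKER_STAGE_DEFAULTS
    trajectory_bootstrap: int = 10_000
    trajectory_seed: int = 7
    trajectory_axis: str = "age"
    grid_step: float = 0.1
    spline_k: int = 10
    mediation_outcomes: tuple[str, ...] = ("tau_suvr", "ptau217")
    mediation_bootstrap: int = 5000
    mediation_seed: int = 11
    ci_level: float = 0.95

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "outdir" not in raw:
            raise PipelineConfigError("run config requires 'outdir'")
        synth = raw.pop("synthetic", None)
        if synth is not None:
            if isinstance(synth, dict):
                base = default_config(
                    seed=synth.get("seed", 0),
                    n_ds=synth.get("n_ds", 348),
                    n_controls=synth.get("n_controls", 42),
                )
                synth = base
            elif not isinstance(synth, CohortConfig):
                raise PipelineConfigError("'synthetic' must be a mapping or CohortConfig")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown run config keys: {sorted(unknown)}")
        for key in ("compare_biomarkers", "trajectory_biomarkers", "mediation_outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synthetic=synth, **raw)


def load_run_config(path) -> RunConfig:
    import yaml

    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise PipelineConfigError(f"run config {path} did not parse to a mapping")
    return RunConfig.from_dict(raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A failure in any stage raises :class:`StageError` naming the stage;
    the CLI maps that to a nonzero exit.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": _jsonable(dataclasses.asdict(config)),
        "stages_run": [],
        "row_counts": {},
    }

    # --- input cohort -----------------------------------------------------
    stage = "simulate"
    try:
        if config.cohort_csv is not None:
            cohort = read_cohort(config.cohort_csv)
            manifest["input"] = {"cohort_csv": str(config.cohort_csv)}
        else:
            synth = config.synthetic if config.synthetic is not None else default_config()
            cohort, sidecar = generate_cohort(synth)
            if config.stages.get("simulate", True):
                write_cohort(cohort, sidecar, outdir / "cohort.csv", outdir / "cohort.truth.json")
                manifest["stages_run"].append("simulate")
            manifest["input"] = {"synthetic_seed": synth.seed}
        manifest["row_counts"]["cohort"] = len(cohort)
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # --- preprocess -------------------------------------------------------
    stage = "preprocess"
    tables = {}
    try:
        if config.stages.get("preprocess", True):
            logger.info("preprocess: deriving EYO and A/T status")
            demographics_table(cohort).to_csv(outdir / "demographics.csv", index=False)
            _write_json(
                outdir / "demographic_tests.json",
                {k: dataclasses.asdict(v) for k, v in compare_demographics(cohort).items()},
            )
            manifest["stages_run"].append("preprocess")
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    def _table(required):
        key = tuple(required)
        if key not in tables:
            tables[key] = build_analysis_table(
                cohort,
                required,
                aao=config.aao,
                centiloid_threshold=config.centiloid_threshold,
                tau_threshold=config.tau_threshold,
            )
        return tables[key]

    # --- group comparisons ------------------------------------------------
    stage = "compare"
    try:
        if config.stages.get("compare", True):
            summary = {}
            for biomarker in config.compare_biomarkers:
                at = _table(["at_group", biomarker])
                (outdir / f"exclusions_compare_{biomarker}.jsonl").write_text(
                    at.log_as_jsonl() + "\n"
                )
                report = compare_by_pathology_group(at, biomarker, ci_level=config.ci_level)
                pd.DataFrame([dataclasses.asdict(c) for c in report.pairwise]).to_csv(
                    outdir / f"comparisons_{biomarker}.csv", index=False
                )
                summary[biomarker] = {
                    "n": at.n,
                    "omnibus": dataclasses.asdict(report.omnibus),
                    "family_size": report.family_size,
                    "skipped": report.skipped,
                    "pairwise": [dataclasses.asdict(c) for c in report.pairwise],
                }
                manifest["row_counts"][f"compare_{biomarker}"] = at.n
            _write_json(outdir / "compare_summary.json", summary)
            manifest["stages_run"].append("compare")
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # --- trajectories -----------------------------------------------------
    stage = "trajectory"
    try:
        if config.stages.get("trajectory", True):
            results = {}
            for biomarker in config.trajectory_biomarkers:
                at = _table([biomarker])
                res = estimate_divergence_age(
                    at.data,
                    biomarker,
                    axis=config.trajectory_axis,
                    n_bootstrap=config.trajectory_bootstrap,
                    grid_step=config.grid_step,
                    k=config.spline_k,
                    seed=config.trajectory_seed,
                    aao=config.aao,
                )
                results[biomarker] = res
                pd.DataFrame(
                    {
                        "grid": res.grid,
                        "ds_curve": res.ds_curve,
                        "control_curve": res.control_curve,
                        "difference_band_low": res.band_low,
                        "difference_band_high": res.band_high,
                    }
                ).to_csv(outdir / f"curves_{biomarker}.csv", index=False)
                manifest["row_counts"][f"trajectory_{biomarker}"] = res.n_ds + res.n_controls
            _write_json(
                outdir / "divergence.json",
                {
                    name: {
                        "divergence_age": res.divergence_age,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "detection_fraction": res.detection_fraction,
                        "n_bootstrap": res.n_bootstrap,
                        "seed": res.seed,
                        "axis": res.axis,
                        "n_ds": res.n_ds,
                        "n_controls": res.n_controls,
                    }
                    for name, res in results.items()
                },
            )
            timings = {}
            names = [n for n in config.trajectory_biomarkers if results[n].detection_fraction >= 0.5]
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    try:
                        cmp = compare_divergence_timing(results[a], results[b])
                    except ValueError as err:
                        timings[f"{a}_vs_{b}"] = {"error": str(err)}
                        continue
                    timings[f"{a}_vs_{b}"] = {
                        "p_value": cmp.p_value,
                        "mean_difference": cmp.mean_difference,
                        "n_used": cmp.n_used,
                        "dropped_fraction": cmp.dropped_fraction,
                        "paired": cmp.paired,
                    }
            _write_json(outdir / "timing.json", timings)
            manifest["stages_run"].append("trajectory")
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # --- mediation ----------------------------------------------------------
    stage = "mediate"
    try:
        if config.stages.get("mediate", True):
            med_out = {}
            rows = []
            for outcome in config.mediation_outcomes:
                spec = MediationSpec(
                    outcome=outcome,
                    n_bootstrap=config.mediation_bootstrap,
                    seed=config.mediation_seed,
                    ci_level=config.ci_level,
                )
                required = [
                    "group",
                    spec.treatment,
                    spec.mediator,
                    spec.outcome,
                    *spec.covariates,
                ]
                at = build_analysis_table(
                    cohort[cohort["group"] == "DS"],
                    required,
                    aao=config.aao,
                    centiloid_threshold=config.centiloid_threshold,
                    tau_threshold=config.tau_threshold,
                )
                result = bootstrap_mediation(spec, at.data)
                med_out[outcome] = {
                    "acme": result.acme,
                    "ade": result.ade,
                    "total_effect": result.total_effect,
                    "proportion_mediated": result.proportion_mediated,
                    "proportion_mediated_truncated": result.proportion_mediated_truncated,
                    "ci": result.ci,
                    "p_values": result.p_values,
                    "analysis_n": result.analysis_n,
                    "stability_flag": result.stability_flag,
                    "dropped_pm_fraction": result.dropped_pm_fraction,
                    "seed": spec.seed,
                }
                rows.append({"outcome": outcome, **{k: v for k, v in med_out[outcome].items() if not isinstance(v, dict)}})
                manifest["row_counts"][f"mediate_{outcome}"] = result.analysis_n
            _write_json(outdir / "mediation.json", med_out)
            pd.DataFrame(rows).to_csv(outdir / "mediation.csv", index=False)
            manifest["stages_run"].append("mediate")
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    _write_json(outdir / "manifest.json", manifest)
    return outdir
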