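"""End-to-end pipeline orchestration and dataset validation.

``run_pipeline`` chains the stages — synthetic data generation, IVRT
simulation and release calibration, IVPT simulation (and optionally skin
calibration), exposure extraction (SC and 0.1%-scaled infundibular
concentrations), population PD fitting and simulation diagnostics — and
records every produced artifact and seed in a JSON manifest.  All tables
use comma-separated UTF-8 CSV with units encoded in the column names
(time_h, cumulative_ug_per_cm2, ...); times are hours from application.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .calibration import fit_release_parameters
from .core import simulate
from .ivpt import build_ivpt_system, infundibular_concentration, layer_accumulation, sc_concentration
from .ivrt import ReleaseProfile, build_ivrt_system, simulate_release
from .pkpd import (
    EmaxParams,
    ErrorModel,
    PopulationModel,
    fit_population,
    residual_diagnostics,
    vpc,
)
from .synthetic import NoiseSpec, StudyDesign, gen_ivrt_dataset, gen_pd_dataset, pd_records_to_frame
from .ivpt import TissueAccumulation

logger = logging.getLogger("dermapk.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_dataset"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Stage toggles, seeds and output location for a full pipeline run."""

    output_dir: str = "results/pipeline"
    seed: int = 0
    run_synth: bool = True
    run_release_calibration: bool = True
    run_pd: bool = True
    noise_cv: float = 0.05
    pd_n_subjects: int = 6
    vpc_replicates: int = 500
    t_end_ivrt: float = 24.0
    t_end_ivpt: float = 48.0


def _default_population() -> PopulationModel:
    # a shrinking response (e.g. SC thickness in um) with modest BSV
    return PopulationModel(
        theta_pop=EmaxParams(emax=-8.0, ec50=50.0, e0=20.0, n=1.0),
        omega2={"emax": 0.04, "e0": 0.0625},
        error=ErrorModel(b=0.08),
        sigmoidicity=False,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the staged workflow; returns (and writes) the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    forms = defaults.example_formulations()
    cell = defaults.default_cell()
    skin = defaults.default_skin()
    transport = defaults.default_transport()
    design = StudyDesign(pd_n_subjects=config.pd_n_subjects)

    def _record(stage, **outputs):
        manifest["stages"][stage] = {"status": "ok", "outputs": sorted(outputs)}
        manifest["outputs"].update({k: str(v) for k, v in outputs.items()})
        logger.info("stage %s complete", stage)

    def _fail(stage, exc):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc), manifest) from exc

    # --- stage: synthetic IVRT data -----------------------------------
    release_data: dict[str, list[ReleaseProfile]] = {}
    try:
        if config.run_synth:
            rows = []
            for i, (name, form) in enumerate(forms.items()):
                noise = NoiseSpec(proportional_cv=config.noise_cv, seed=config.seed + i)
                profiles, truth = gen_ivrt_dataset(form, cell, design, noise)
                release_data[name] = profiles
                rows.append(ReleaseProfile.collection_to_frame(profiles))
                (out / f"ivrt_truth_{name}.json").write_text(json.dumps(truth, indent=2))
            path = out / "ivrt_synthetic.csv"
            pd.concat(rows, ignore_index=True).to_csv(path, index=False)
            _record("gen_synth_ivrt", ivrt_synthetic=path)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail("gen_synth_ivrt", exc)

    # --- stage: IVRT simulation + release calibration ------------------
    fitted_forms = dict(forms)
    try:
        t_grid = np.linspace(0.0, config.t_end_ivrt, 97)
        sim_rows = []
        fits = {}
        for name, form in forms.items():
            prof = simulate_release(build_ivrt_system(form, cell), t_grid)
            sim_rows.append(prof.to_frame())
            if config.run_release_calibration and name in release_data:
                fit = fit_release_parameters(release_data[name], form, cell, seed=config.seed)
                fits[name] = fit.to_dict()
                fitted_forms[name] = form.with_params(**fit.values)
        sim_path = out / "ivrt_simulated.csv"
        pd.concat(sim_rows, ignore_index=True).to_csv(sim_path, index=False)
        outputs = {"ivrt_simulated": sim_path}
        if fits:
            fit_path = out / "release_fits.json"
            fit_path.write_text(json.dumps(fits, indent=2))
            outputs["release_fits"] = fit_path
        _record("ivrt", **outputs)
    except Exception as exc:  # noqa: BLE001
        _fail("ivrt", exc)

    # --- stage: IVPT simulation + exposure extraction ------------------
    exposures = {}
    try:
        t_grid = np.linspace(0.0, config.t_end_ivpt, 97)
        acc_rows, exp_rows = [], []
        for name, form in fitted_forms.items():
            system = build_ivpt_system(form, skin, transport)
            res = simulate(system, t_grid)
            acc = layer_accumulation(res, skin)
            acc.formulation = name
            acc_rows.append(acc.to_frame())
            c_sc = sc_concentration(res, skin)
            exposures[name] = (t_grid, c_sc)
            exp_rows.append(
                pd.DataFrame(
                    {
                        "formulation": name,
                        "time_h": t_grid,
                        "sc_concentration_ug_mL": c_sc,
                        "infundibular_concentration_ug_mL": infundibular_concentration(c_sc),
                    }
                )
            )
        acc_path = out / "ivpt_accumulation.csv"
        exp_path = out / "exposure.csv"
        pd.concat(acc_rows, ignore_index=True).to_csv(acc_path, index=False)
        pd.concat(exp_rows, ignore_index=True).to_csv(exp_path, index=False)
        _record("ivpt", ivpt_accumulation=acc_path, exposure=exp_path)
    except Exception as exc:  # noqa: BLE001
        _fail("ivpt", exc)

    # --- stage: population PD ------------------------------------------
    if config.run_pd:
        try:
            pop_true = _default_population()
            records, truth = gen_pd_dataset(pop_true, exposures, design, seed=config.seed)
            pd_path = out / "pd_synthetic.csv"
            pd_records_to_frame(records).to_csv(pd_path, index=False)
            fit = fit_population(records, pop_true, seed=config.seed)
            fit_path = out / "pd_fit.json"
            fit_path.write_text(
                json.dumps(
                    {
                        "theta_pop": fit["model"].theta_pop.__dict__.copy(),
                        "omega2": dict(fit["model"].omega2),
                        "b": fit["model"].error.b,
                        "report": fit["report"].to_dict(),
                        "converged": fit["converged"],
                        "seed": config.seed,
                    },
                    indent=2,
                )
            )
            t_obs = np.asarray(design.pd_observation_times, float)
            t_exp, c_exp = exposures[design.pd_formulations[0]]
            vpc_df = vpc(
                fit["model"],
                t_obs,
                np.interp(t_obs, t_exp, c_exp),
                n_subjects=config.pd_n_subjects,
                n_replicates=max(100, config.vpc_replicates),
                seed=config.seed,
            )
            vpc_path = out / "pd_vpc.csv"
            vpc_df.to_csv(vpc_path, index=False)
            diag = residual_diagnostics(records, fit["model"], fit["ebes"], seed=config.seed)
            diag_path = out / "pd_diagnostics.csv"
            diag.to_csv(diag_path, index=False)
            _record("pd", pd_synthetic=pd_path, pd_fit=fit_path, pd_vpc=vpc_path, pd_diagnostics=diag_path)
        except Exception as exc:  # noqa: BLE001
            _fail("pd", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest


_SCHEMAS = {
    "release": {
        "columns": ["formulation", "time_h", "cumulative_ug_per_cm2"],
        "value_columns": ["cumulative_ug_per_cm2"],
        "group": ["formulation", "replicate"],
    },
    "accumulation": {
        "columns": ["formulation", "time_h", "epidermis_ug_per_mg", "dermis_ug_per_mg", "receptor_ug"],
        "value_columns": ["epidermis_ug_per_mg", "dermis_ug_per_mg", "receptor_ug"],
        "group": ["formulation", "replicate"],
    },
    "pd": {
        "columns": ["subject_id", "formulation", "time_h", "endpoint", "value"],
        "value_columns": ["value"],
        "group": ["subject_id"],
    },
}


def validate_dataset(path, schema_name: str) -> dict:
    """Check a pipeline CSV against its schema; returns a findings report."""
    if schema_name not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; options: {sorted(_SCHEMAS)}")
    schema = _SCHEMAS[schema_name]
    findings = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        return {"path": str(path), "schema": schema_name, "valid": False,
                "findings": [{"kind": "parse_error", "detail": str(exc)}]}
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        findings.append({"kind": "missing_columns", "detail": missing})
    else:
        group_cols = [c for c in schema["group"] if c in df.columns]
        grouped = df.groupby(group_cols, sort=False) if group_cols else [(None, df)]
        for key, g in grouped:
            t = g["time_h"].to_numpy()
            if np.any(np.diff(t) < 0):
                findings.append({"kind": "times_not_sorted", "group": str(key)})
        for col in schema["value_columns"]:
            bad = df.index[df[col] < 0].tolist()
            if bad:
                findings.append({"kind": "negative_value", "column": col, "rows": bad[:20]})
            nonfinite = df.index[~np.isfinite(df[col])].tolist()
            if nonfinite:
                findings.append({"kind": "non_finite_value", "column": col, "rows": nonfinite[:20]})
    return {
        "path": str(path),
        "schema": schema_name,
        "valid": not findings,
        "findings": findings,
        "n_rows": int(len(df)),
    }
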