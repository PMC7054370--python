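"""End-to-end orchestration: simulate/ingest, phenotype, QC, univariate
models, shrinkage fits, cross-validated evaluation and panel selection.

A single global seed fans out to per-stage seeds through a spawned
``numpy.random.SeedSequence`` counter; all seeds, the configuration echo and
output hashes go into a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import cv_report, crossvalidate
from .horseshoe import ShrinkagePrior, fit_shrinkage
from .phenotypes import derive_phenotypes, progression_rate
from .qc import clustered_correlation, gaussianise, run_qc
from .selection import forward_select, report_selection
from .simulate import (SimulationConfig, apply_enrichment_sampling,
                       generate_cohort, write_cohort)
from .univariate import COVARIATE_SETS, univariate_table

CKD_STAGE_BOUNDS = (90.0, 60.0)  # G1 above, G2 between, G3 below (>=30)


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    outdir: str = "renalpanel_run"
    outcome: str = "final_egfr"  # or "lt30" / "lt45"
    covariate_sets: tuple = ("basic",)
    apply_enrichment: bool = False
    cv_folds: int = 10
    prior: ShrinkagePrior = field(default_factory=ShrinkagePrior)
    selection_max_size: int = 5
    selection_draws: int = 400
    compartment: str = "serum"  # biomarker set modelled in the panel stage

    @classmethod
    def from_yaml(cls, path):
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        prior = ShrinkagePrior(**raw.pop("prior", {}))
        return cls(simulation=sim, prior=prior, **raw)


def stage_seeds(seed: int, n: int = 8):
    """Deterministic per-stage seeds below 2^31 from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def assemble_analysis_frame(participants, phenotypes: pd.DataFrame,
                            markers: pd.DataFrame) -> pd.DataFrame:
    """Merge covariates, phenotypes and processed biomarkers into the
    modelling frame: continuous covariates Gaussianised, binary covariates
    0/1, study-day ACR Gaussianised, outcome final eGFR standardized."""
    rows = []
    for p in participants:
        acr0 = [v for (d, v) in p.acr_series if abs(d) < 1.0]
        rows.append({
            "id": p.id,
            "sex": 1.0 if p.sex == "female" else 0.0,
            "age_raw": p.age,
            "diabetes_duration_raw": p.diabetes_duration,
            "acr_raw": acr0[0] if acr0 else np.nan,
            "bmi_raw": p.covariates["bmi"],
            "sbp_raw": p.covariates["sbp"],
            "dbp_raw": p.covariates["dbp"],
            "hba1c_raw": p.covariates["hba1c"],
            "hdl_raw": p.covariates["hdl"],
            "total_chol_raw": p.covariates["total_chol"],
            "ever_smoker": float(p.covariates["ever_smoker"]),
            "on_acei_arb": float(p.covariates["on_acei_arb"]),
        })
    frame = pd.DataFrame(rows).set_index("id")
    frame = frame.join(phenotypes, how="inner")

    for name in ("age", "diabetes_duration", "acr", "bmi", "sbp", "dbp",
                 "hba1c", "hdl", "total_chol"):
        frame[name] = gaussianise(frame[f"{name}_raw"].to_numpy())
    for name in ("study_day_egfr", "weighted_historical_egfr", "followup_years"):
        raw = frame[name].to_numpy()
        frame[f"{name}_raw"] = raw
        frame[name] = gaussianise(raw)

    fe = frame["final_egfr"].to_numpy()
    frame["final_egfr_raw"] = fe
    frame["final_egfr_std"] = (fe - np.nanmean(fe)) / np.nanstd(fe)
    frame = frame.join(markers, how="left")
    return frame


def outcome_column(frame: pd.DataFrame, outcome: str):
    if outcome == "final_egfr":
        return "final_egfr_std", "linear"
    if outcome == "lt30":
        return "progressed_lt30", "logistic"
    if outcome == "lt45":
        return "progressed_lt45", "logistic"
    raise ValueError(f"unknown outcome {outcome!r}")


def design_matrices(frame: pd.DataFrame, covariate_set: str, marker_names):
    """Complete-case design matrices (standardized) for the panel models."""
    covs = COVARIATE_SETS[covariate_set]
    cols = covs + list(marker_names)
    d = frame.dropna(subset=cols)
    X_cov = d[covs].to_numpy(float)
    X_cov = (X_cov - X_cov.mean(axis=0)) / np.where(X_cov.std(axis=0) > 0,
                                                    X_cov.std(axis=0), 1.0)
    X_bio = d[list(marker_names)].to_numpy(float)
    return d, X_cov, X_bio


def cohort_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Participant characteristics at study day stratified by CKD stage
    (G1 >= 90, G2 60-90, G3 < 60; boundaries resolve to the lower stage
    index).  Continuous rows report median (IQR), categorical rows %."""
    egfr = frame["study_day_egfr_raw"]
    stage = np.where(egfr >= CKD_STAGE_BOUNDS[0], "G1",
                     np.where(egfr >= CKD_STAGE_BOUNDS[1], "G2", "G3"))
    cont = {"Age (years)": "age_raw",
            "Diabetes duration (years)": "diabetes_duration_raw",
            "eGFR": "study_day_egfr_raw",
            "Weighted historical eGFR": "weighted_historical_egfr_raw",
            "Length of follow-up (years)": "followup_years_raw",
            "ACR (mg/mmol)": "acr_raw",
            "HbA1c (mmol/mol)": "hba1c_raw",
            "BMI (kg/m2)": "bmi_raw",
            "Systolic BP (mmHg)": "sbp_raw",
            "Diastolic BP (mmHg)": "dbp_raw"}
    cat = {"Sex (female), %": "sex", "Ever smoker, %": "ever_smoker",
           "On ACEi/ARB, %": "on_acei_arb"}
    groups = ["G1", "G2", "G3", "All"]
    out = {}
    for g in groups:
        mask = np.ones(len(frame), bool) if g == "All" else stage == g
        col = {"n": int(mask.sum())}
        for label, c in cont.items():
            x = frame.loc[mask, c].dropna()
            if len(x) == 0:
                col[label] = "-"
            else:
                col[label] = (f"{x.median():.1f} "
                              f"({x.quantile(0.25):.1f}, {x.quantile(0.75):.1f})")
        for label, c in cat.items():
            x = frame.loc[mask, c].dropna()
            col[label] = f"{100 * x.mean():.1f}" if len(x) else "-"
        out[g] = col
    tab = pd.DataFrame(out)
    keep = [g for g in groups if g == "All" or tab.loc["n", g] >= 5]
    return tab[keep]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Writes, under ``config.outdir``: the simulated cohort tables,
    phenotypes.tsv, qc_report.json, the processed marker matrix, the
    clustered correlation matrix, the univariate association table, the
    cross-validated performance table, selection_path.tsv, cohort_summary.tsv
    and manifest.json.  Any stage failure aborts with the stage name; files
    written before the failure are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {"version": __version__, "seed": config.seed,
                "stage_seeds": seeds, "config": _as_jsonable(config),
                "stages": []}
    stage = "simulate"
    try:
        sim = dataclasses.replace(config.simulation, seed=seeds[0])
        participants, panel, truth = generate_cohort(sim)
        if config.apply_enrichment:
            participants, panel, truth = apply_enrichment_sampling(
                participants, panel, sim.enrichment_fractions, seeds[1],
                truth=truth)
        write_cohort(out, participants, panel, truth)
        manifest["stages"].append("simulate")

        stage = "phenotype"
        phenotypes = derive_phenotypes(participants)
        phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
        for thr, col in ((30, "progressed_lt30"), (45, "progressed_lt45")):
            ev, risk, pct = progression_rate(phenotypes[col])
            manifest[f"progression_lt{thr}"] = {"events": ev, "at_risk": risk,
                                                "percent": pct}
        manifest["stages"].append("phenotype")

        stage = "qc"
        report, processed = run_qc(panel)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t")
        (out / "qc_report.json").write_text(
            report.to_frame().to_json(orient="index"))
        processed.to_csv(out / "markers_processed.tsv", sep="\t")
        corr, order = clustered_correlation(processed)
        corr.to_csv(out / "marker_correlation_clustered.tsv", sep="\t")
        manifest["stages"].append("qc")

        stage = "assemble"
        frame = assemble_analysis_frame(participants, phenotypes, processed)
        cohort_summary(frame).to_csv(out / "cohort_summary.tsv", sep="\t")
        manifest["stages"].append("assemble")

        stage = "univariate"
        ycol, family = outcome_column(frame, config.outcome)
        markers = [m for m in report.included_names]
        uni = univariate_table(frame.dropna(subset=[ycol]), markers, ycol,
                               family=family,
                               covariate_sets=tuple(config.covariate_sets))
        uni.to_csv(out / "univariate_associations.tsv", sep="\t")
        manifest["stages"].append("univariate")

        stage = "panel"
        comp_markers = [m for m, c in zip(panel.marker_names, panel.compartment)
                        if c == config.compartment and m in set(markers)]
        reports = []
        fits = {}
        for cs in config.covariate_sets:
            d, X_cov, X_bio = design_matrices(frame.dropna(subset=[ycol]),
                                              cs, comp_markers)
            y = d[ycol].to_numpy(float)
            cv_ref = crossvalidate(X_cov, None, y, family, config.prior,
                                   config.cv_folds, seeds[2])
            cv_full = crossvalidate(X_cov, X_bio, y, family, config.prior,
                                    config.cv_folds, seeds[2],
                                    folds=cv_ref["folds"])
            rep = cv_report(f"{config.compartment} biomarkers", cs, family, y,
                            cv_full, cv_ref)
            reports.append(rep)
            fit = fit_shrinkage(X_cov, X_bio, y, family, config.prior, seeds[3])
            fit.save(out / f"fit_{cs}_draws.csv", out / f"fit_{cs}_diag.json")
            fits[cs] = (fit, X_cov, X_bio)
        perf = pd.DataFrame([{k: v for k, v in vars(r).items() if k != "folds"}
                             for r in reports])
        perf.to_csv(out / "cv_performance.tsv", sep="\t", index=False)
        manifest["stages"].append("panel")

        stage = "select"
        cs0 = config.covariate_sets[0]
        fit, X_cov, X_bio = fits[cs0]
        path = forward_select(fit, X_cov, X_bio,
                              max_size=min(config.selection_max_size, fit.n_bio),
                              marker_names=comp_markers,
                              n_draws=config.selection_draws, seed=seeds[4])
        report_selection(path, plot_path=out / "selection_power.svg").to_csv(
            out / "selection_path.tsv", sep="\t", index=False)
        manifest["stages"].append("select")
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["outputs"] = {f.name: _sha256(f) for f in sorted(out.iterdir())
                           if f.suffix in (".tsv", ".json", ".csv")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"outdir": str(out), "manifest": manifest, "phenotypes": phenotypes,
            "qc": report, "frame": frame, "cv": reports, "selection": path}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
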