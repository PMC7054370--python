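"""Seeded synthetic cohort generator.

Emulates the statistical structure of an eGFR-enriched type 1 diabetes
biomarker study: clustered log-normal biomarkers (four clusters plus one
very highly correlated TNF-family pair), latent final eGFR driven by a small
number of truly informative markers, creatinine series obtained by inverting
the CKD-EPI equation along a linear latent eGFR trajectory with
multiplicative visit noise, ACR series log-normally distributed and coupled
to the latent decline, detection-limit censoring, blinded duplicate aliquots
with a target intraclass correlation, rare progression events, and
eGFR-stratified enrichment sampling.

All time coordinates are days relative to the study (biosample) day; the
writers convert to ISO-8601 dates against a nominal recruitment date.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phenotypes import creatinine_from_egfr, ckd_epi_egfr

STUDY_DATE = np.datetime64("2012-01-15")
EGFR_ENRICH_CUT = 75.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the target study design: 9 serum + 13 urine markers in
    four correlation clusters with one TNF-family pair at r = 0.80,
    enrichment sampling probabilities (0.5, 0.25) below/above eGFR 75,
    ~2.5% progression to eGFR < 30, median follow-up ~5.1 years, and
    duplicate aliquots on 48 participants.
    """

    n_participants: int = 800
    seed: int = 0
    n_serum_markers: int = 9
    n_urine_markers: int = 13
    n_clusters: int = 4
    within_cluster_corr: float = 0.5
    cross_cluster_corr: float = 0.05
    tnf_pair_corr: float = 0.80
    # (marker index, effect in SD of final eGFR per SD of log marker)
    true_effect_markers: tuple = ((0, -0.4), (2, -0.4))
    lod_quantile: float = 0.02
    duplicate_icc_target: float = 0.9
    n_duplicates: int = 48
    followup_years: float = 5.1
    retro_years: float = 5.4
    visits_per_year: float = 2.5
    acr_visits_per_year: float = 1.0
    progression_base_rate: float = 0.025
    enrichment_fractions: tuple = (0.5, 0.25)
    acr_coupling: float = 0.8
    egfr_noise_cv: float = 0.05
    hospital_visit_frac: float = 0.02
    outcome_sd: float = 12.0
    outcome_resid_sd: float = 0.5

    def validate(self):
        p = self.n_serum_markers + self.n_urine_markers
        if self.n_participants < 20:
            raise ValueError("n_participants too small (need at least 2x CV folds)")
        if not (0 <= self.within_cluster_corr < 1):
            raise ValueError("within_cluster_corr must be in [0, 1)")
        if not all(0 < f <= 1 for f in self.enrichment_fractions):
            raise ValueError("enrichment fractions must be in (0, 1]")
        if not (0 <= self.lod_quantile < 1):
            raise ValueError("lod_quantile must be in [0, 1)")
        if not (0 < self.duplicate_icc_target <= 1):
            raise ValueError("duplicate_icc_target must be in (0, 1]")
        for idx, _ in self.true_effect_markers:
            if not (0 <= idx < p):
                raise ValueError(f"effect marker index {idx} out of range")
        if np.linalg.eigvalsh(build_marker_correlation(self)).min() <= 1e-10:
            raise ValueError("requested cluster structure is not positive definite")


@dataclass
class ParticipantRecord:
    id: str
    sex: str
    age: float
    diabetes_duration: float
    creatinine_series: list  # (day, value umol/l, in_hospital)
    acr_series: list  # (day, ACR mg/mmol)
    covariates: dict
    rrt_day: Optional[float] = None
    creatinine_unit: str = "umol/l"


@dataclass
class BiomarkerPanel:
    marker_names: list
    compartment: list  # "serum"/"urine" per marker
    values: np.ndarray  # participants x markers; NaN = below detection limit
    detection_limit: np.ndarray
    urinary_creatinine: np.ndarray  # mmol/l per participant
    duplicate_ids: list
    duplicate_values: np.ndarray  # len(duplicate_ids) x markers
    participant_ids: list

    def subset(self, keep: np.ndarray) -> "BiomarkerPanel":
        ids = [pid for pid, k in zip(self.participant_ids, keep) if k]
        idset = set(ids)
        dup_keep = [i for i, pid in enumerate(self.duplicate_ids) if pid in idset]
        return BiomarkerPanel(
            marker_names=self.marker_names,
            compartment=self.compartment,
            values=self.values[keep],
            detection_limit=self.detection_limit,
            urinary_creatinine=self.urinary_creatinine[keep],
            duplicate_ids=[self.duplicate_ids[i] for i in dup_keep],
            duplicate_values=self.duplicate_values[dup_keep],
            participant_ids=ids,
        )


def build_marker_correlation(config: SimulationConfig) -> np.ndarray:
    """Block correlation matrix: clusters assigned contiguously, uniform
    within/cross-cluster correlations, and the serum TNF-family pair
    (markers 0 and 1) raised to ``tnf_pair_corr``."""
    p = config.n_serum_markers + config.n_urine_markers
    sizes = np.full(config.n_clusters, p // config.n_clusters)
    sizes[: p % config.n_clusters] += 1
    labels = np.repeat(np.arange(config.n_clusters), sizes)
    same = labels[:, None] == labels[None, :]
    r = np.where(same, config.within_cluster_corr, config.cross_cluster_corr)
    if p >= 2:
        r[0, 1] = r[1, 0] = config.tnf_pair_corr
    np.fill_diagonal(r, 1.0)
    return r


def _marker_names(config: SimulationConfig):
    serum = [f"S{j+1:02d}" for j in range(config.n_serum_markers)]
    urine = [f"U{j+1:02d}" for j in range(config.n_urine_markers)]
    names = serum + urine
    if config.n_serum_markers >= 2:
        names[0], names[1] = "S_TNFR1", "S_CD27"
    comp = ["serum"] * config.n_serum_markers + ["urine"] * config.n_urine_markers
    return names, comp


def _calibrate_drift(latent_no_drift, baseline, noise_sd, target_rate):
    """Bisection for the global downward drift that sets the expected
    prevalence of final eGFR < 30 among those at risk to the target rate."""
    from scipy.stats import norm

    at_risk = baseline >= 30.0

    def rate(drift):
        z = (30.0 - (latent_no_drift[at_risk] - drift)) / noise_sd
        return float(np.mean(norm.cdf(z)))

    lo, hi = -60.0, 90.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimulationConfig):
    """Generate (participants, biomarker panel, truth record).

    Deterministic given the config (including its seed).  The truth record
    retains every latent quantity needed for recovery tests: uncensored log
    marker values, standardized marker scores, per-marker effects, latent
    final eGFR, baseline eGFR and the calibrated drift.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    p = config.n_serum_markers + config.n_urine_markers
    names, comp = _marker_names(config)

    sex = np.where(rng.random(n) < 0.49, "female", "male")
    age = np.clip(rng.normal(48.0, 14.0, n), 18.0, 80.0)
    duration = np.clip(age - rng.normal(26.0, 10.0, n), 1.0, None)
    baseline = np.clip(118.0 - 0.62 * age + rng.normal(0.0, 16.0, n), 30.0, 140.0)

    # clustered standard-normal marker scores, log-normal concentrations
    corr = build_marker_correlation(config)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ chol.T
    log_mu = rng.uniform(0.0, 3.0, p)
    log_sd = rng.uniform(0.4, 0.8, p)
    log_values = log_mu + log_sd * z

    effects = np.zeros(p)
    for idx, eff in config.true_effect_markers:
        effects[idx] = eff
    contrib = z @ effects
    eps = rng.normal(0.0, config.outcome_resid_sd, n)
    latent_no_drift = baseline + config.outcome_sd * (contrib + eps)
    noise_sd = config.outcome_sd * config.outcome_resid_sd
    drift = _calibrate_drift(baseline + config.outcome_sd * contrib, baseline,
                             noise_sd, config.progression_base_rate)
    final_lat = np.maximum(latent_no_drift - drift, 8.0)

    followup = np.clip(rng.normal(config.followup_years, 0.6, n), 2.5, 6.5)
    retro_len = np.clip(rng.normal(config.retro_years, 0.5, n), 2.0, 7.0)
    rrt_day = np.full(n, np.nan)

    participants = []
    damage = (baseline - final_lat) / config.outcome_sd  # standardized decline
    for i in range(n):
        pid = f"P{i:05d}"
        slope_per_day = (final_lat[i] - baseline[i]) / (followup[i] * 365.25)
        # visit days: Poisson-spaced over retrospective and prospective windows
        days = _poisson_visits(rng, -retro_len[i] * 365.25, followup[i] * 365.25,
                               config.visits_per_year)
        days = np.unique(np.concatenate([days, [0.0]]))
        while np.sum(days > 0) < 3:
            days = np.unique(np.append(days, rng.uniform(30.0, followup[i] * 365.25)))
        traj = np.maximum(baseline[i] + slope_per_day * days, 10.0)
        if final_lat[i] <= 12.0:
            # trajectory reaches kidney failure: RRT when crossing eGFR 15
            cross = (15.0 - baseline[i]) / slope_per_day if slope_per_day < 0 else np.nan
            if np.isfinite(cross) and 0 < cross < followup[i] * 365.25:
                rrt_day[i] = cross
                days = days[days <= cross]
                traj = traj[: len(days)]
        noise = np.exp(rng.normal(0.0, config.egfr_noise_cv, len(days)))
        hosp = rng.random(len(days)) < config.hospital_visit_frac
        hosp[np.argmin(np.abs(days))] = False  # keep the study-day reading clean
        age_at = age[i] + days / 365.25
        cre = creatinine_from_egfr(np.maximum(traj, 10.0), age_at,
                                   [sex[i]] * len(days)) * noise
        cre = cre * np.where(hosp, rng.uniform(1.3, 2.2, len(days)), 1.0)
        cre_series = [(float(d), float(c), bool(h)) for d, c, h in zip(days, cre, hosp)]

        acr_days = _poisson_visits(rng, -retro_len[i] * 365.25,
                                   (rrt_day[i] if np.isfinite(rrt_day[i])
                                    else followup[i] * 365.25),
                                   config.acr_visits_per_year)
        acr_days = np.unique(np.concatenate([acr_days, [0.0]]))
        log_acr_mu = np.log(0.45) + config.acr_coupling * damage[i] + rng.normal(0.0, 1.2)
        trend = 0.25 * max(damage[i], 0.0) / 365.25 / config.followup_years * 365.25
        log_acr = (log_acr_mu + trend * np.maximum(acr_days, 0.0) / 365.25
                   + rng.normal(0.0, 0.35, len(acr_days)))
        acr_series = [(float(d), float(max(np.exp(v), 0.02)))
                      for d, v in zip(acr_days, log_acr)]

        covariates = {
            "bmi": float(np.clip(rng.normal(26.8, 4.3), 16, 50)),
            "sbp": float(np.clip(rng.normal(130 + 2.5 * damage[i], 14), 90, 210)),
            "dbp": float(np.clip(rng.normal(75, 9), 45, 120)),
            "hba1c": float(np.clip(rng.normal(69 + 2.0 * damage[i], 13), 35, 140)),
            "hdl": float(np.clip(rng.normal(1.55, 0.42), 0.5, 3.5)),
            "total_chol": float(np.clip(rng.normal(4.5, 0.9), 2.0, 9.0)),
            "ever_smoker": bool(rng.random() < 0.64),
            "on_acei_arb": bool(rng.random() < 0.3 + 0.15 * (damage[i] > 0.5)),
        }
        participants.append(ParticipantRecord(
            id=pid, sex=str(sex[i]), age=float(age[i]),
            diabetes_duration=float(duration[i]),
            creatinine_series=cre_series, acr_series=acr_series,
            covariates=covariates,
            rrt_day=float(rrt_day[i]) if np.isfinite(rrt_day[i]) else None,
        ))

    # measurement error common to primary and duplicate aliquots sets the ICC
    icc = config.duplicate_icc_target
    meas_sd = log_sd * np.sqrt((1.0 - icc) / icc)
    e1 = rng.normal(0.0, 1.0, (n, p)) * meas_sd
    values = np.exp(log_values + e1)
    n_dup = min(config.n_duplicates, n)
    dup_rows = rng.choice(n, size=n_dup, replace=False)
    e2 = rng.normal(0.0, 1.0, (n_dup, p)) * meas_sd
    dup_values = np.exp(log_values[dup_rows] + e2)

    detection_limit = np.quantile(values, config.lod_quantile, axis=0)
    censored = values < detection_limit
    values = np.where(censored, np.nan, values)
    dup_values = np.where(dup_values < detection_limit, np.nan, dup_values)

    urinary_cre = np.exp(rng.normal(np.log(9.0), 0.5, n))

    panel = BiomarkerPanel(
        marker_names=names, compartment=comp, values=values,
        detection_limit=detection_limit, urinary_creatinine=urinary_cre,
        duplicate_ids=[f"P{i:05d}" for i in dup_rows],
        duplicate_values=dup_values,
        participant_ids=[p_.id for p_ in participants],
    )
    truth = {
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "effects": effects.tolist(),
        "drift": float(drift),
        "baseline_egfr": baseline.tolist(),
        "final_egfr_latent": final_lat.tolist(),
        "marker_scores": z.tolist(),
        "log_values_uncensored": log_values.tolist(),
        "damage": damage.tolist(),
        "rrt_day": [None if not np.isfinite(d) else float(d) for d in rrt_day],
    }
    return participants, panel, truth


def _poisson_visits(rng, start_day, end_day, rate_per_year):
    n = rng.poisson(max(end_day - start_day, 0.0) / 365.25 * rate_per_year)
    return np.sort(rng.uniform(start_day, end_day, n))


def apply_enrichment_sampling(participants, panel: BiomarkerPanel,
                              fractions: Sequence[float], seed: int,
                              study_day_egfr: Optional[np.ndarray] = None,
                              truth: Optional[dict] = None):
    """eGFR-stratified enrichment subsampling.

    Each participant is included independently with probability
    ``fractions[0]`` if their study-day eGFR is below 75 and ``fractions[1]``
    otherwise, mirroring the 50%/25% enrichment design.
    """
    if not all(0 <= f <= 1 for f in fractions):
        raise ValueError("fractions must be probabilities")
    if study_day_egfr is None:
        study_day_egfr = np.array([_study_day_egfr(p) for p in participants])
    rng = np.random.default_rng(seed)
    prob = np.where(study_day_egfr < EGFR_ENRICH_CUT, fractions[0], fractions[1])
    keep = rng.random(len(participants)) < prob
    sub_participants = [p for p, k in zip(participants, keep) if k]
    sub_panel = panel.subset(keep)
    sub_truth = None
    if truth is not None:
        sub_truth = dict(truth)
        for key in ("baseline_egfr", "final_egfr_latent", "marker_scores",
                    "log_values_uncensored", "damage", "rrt_day"):
            sub_truth[key] = [v for v, k in zip(truth[key], keep) if k]
    return sub_participants, sub_panel, sub_truth


def _study_day_egfr(p: ParticipantRecord) -> float:
    days = np.array([d for d, _, h in p.creatinine_series if not h])
    vals = np.array([v for _, v, h in p.creatinine_series if not h])
    i = int(np.argmin(np.abs(days)))
    return float(ckd_epi_egfr(vals[i], p.age + days[i] / 365.25, p.sex,
                              unit=p.creatinine_unit))


# ---------------------------------------------------------------- I/O


def write_cohort(outdir, participants, panel: BiomarkerPanel, truth=None):
    """Write participants.tsv, labs_long.tsv, biomarkers.tsv (+ truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    prow = []
    for p in participants:
        row = {"id": p.id, "sex": p.sex, "age_years": p.age,
               "diabetes_duration_years": p.diabetes_duration,
               "study_day": str(STUDY_DATE),
               "rrt_start": _iso(p.rrt_day)}
        row.update(p.covariates)
        prow.append(row)
    pd.DataFrame(prow).to_csv(outdir / "participants.tsv", sep="\t", index=False)

    lrow = []
    for p in participants:
        for day, val, hosp in p.creatinine_series:
            lrow.append({"id": p.id, "date": _iso(day), "analyte": "creatinine",
                         "value": val, "unit": p.creatinine_unit,
                         "in_hospital": int(hosp)})
        for day, val in p.acr_series:
            lrow.append({"id": p.id, "date": _iso(day), "analyte": "acr",
                         "value": val, "unit": "mg/mmol", "in_hospital": 0})
    pd.DataFrame(lrow).to_csv(outdir / "labs_long.tsv", sep="\t", index=False)

    bio = pd.DataFrame(panel.values, columns=panel.marker_names)
    bio.insert(0, "id", panel.participant_ids)
    bio["urinary_creatinine_mmol_l"] = panel.urinary_creatinine
    bio["aliquot"] = "primary"
    dup = pd.DataFrame(panel.duplicate_values, columns=panel.marker_names)
    dup.insert(0, "id", panel.duplicate_ids)
    dup["urinary_creatinine_mmol_l"] = np.nan
    dup["aliquot"] = "duplicate"
    lod = pd.DataFrame([panel.detection_limit], columns=panel.marker_names)
    lod.insert(0, "id", "_detection_limit")
    lod["urinary_creatinine_mmol_l"] = np.nan
    lod["aliquot"] = "lod"
    meta = pd.DataFrame([panel.compartment], columns=panel.marker_names)
    meta.insert(0, "id", "_compartment")
    meta["urinary_creatinine_mmol_l"] = np.nan
    meta["aliquot"] = "meta"
    pd.concat([meta, lod, bio, dup]).to_csv(outdir / "biomarkers.tsv",
                                            sep="\t", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth))


def _iso(day):
    if day is None:
        return ""
    return str(STUDY_DATE + np.timedelta64(int(round(day)), "D"))
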