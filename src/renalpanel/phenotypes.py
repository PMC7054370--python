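"""Renal phenotype derivation from longitudinal creatinine and ACR records.

All eGFR values are in ml/min per 1.73 m^2.  Serum creatinine is accepted in
micromol/l (``umol/l``, the clinical-laboratory convention used throughout
the package) or mg/dl.  Renal replacement therapy (RRT) is handled with the
convention that its initiation corresponds to an achieved eGFR of 10, with
all subsequent creatinine readings censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

UMOL_PER_MGDL = 88.4

# micro/macroalbuminuria boundaries for urinary albumin/creatinine ratio, mg/mmol
ACR_MICRO = 3.39
ACR_MACRO = 33.9

RRT_EGFR = 10.0
FINAL_WINDOW_DAYS = 182
DURABILITY_DAYS = 90


def ckd_epi_egfr(creatinine, age, sex, unit: str = "umol/l"):
    """Estimated GFR from the CKD-EPI 2009 creatinine equation.

    Parameters
    ----------
    creatinine : float or array
        Serum creatinine concentration, strictly positive.
    age : float or array
        Age in years, strictly positive.
    sex : str or array
        ``"female"`` / ``"male"`` (or ``"F"`` / ``"M"``).
    unit : str
        ``"umol/l"`` (default) or ``"mg/dl"``.

    Returns
    -------
    float or ndarray
        eGFR in ml/min per 1.73 m^2.  No race coefficient is applied.
    """
    scr = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if unit in ("umol/l", "umol/L", "micromol/l"):
        scr = scr / UMOL_PER_MGDL
    elif unit not in ("mg/dl", "mg/dL"):
        raise ValueError(f"unknown creatinine unit {unit!r}")

    female = _is_female(sex)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def creatinine_from_egfr(egfr, age, sex, unit: str = "umol/l"):
    """Invert the CKD-EPI 2009 equation: creatinine giving the target eGFR.

    Exact inverse of :func:`ckd_epi_egfr` (the equation is strictly
    decreasing in creatinine, so the inverse is unique).
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    female = _is_female(sex)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    a = 141.0 * 0.993 ** age * np.where(female, 1.018, 1.0)
    # egfr <= a corresponds to scr >= kappa (the -1.209 branch)
    ratio = np.where(egfr <= a, (egfr / a) ** (-1.0 / 1.209), (egfr / a) ** (1.0 / alpha))
    scr = kappa * ratio
    if unit in ("umol/l", "umol/L", "micromol/l"):
        scr = scr * UMOL_PER_MGDL
    elif unit not in ("mg/dl", "mg/dL"):
        raise ValueError(f"unknown creatinine unit {unit!r}")
    if scr.ndim == 0:
        return float(scr)
    return scr


def _is_female(sex):
    sexarr = np.asarray(sex)
    if sexarr.dtype.kind in "US":
        low = np.char.lower(sexarr.astype(str))
        female = np.isin(low, ("female", "f"))
        male = np.isin(low, ("male", "m"))
        if not np.all(female | male):
            raise ValueError("sex must be 'female' or 'male'")
        return female if sexarr.ndim else bool(female)
    return sexarr.astype(bool)


def weighted_historical_egfr(
    delta_years: Sequence[float],
    egfr_values: Sequence[float],
    study_day_egfr: float,
    weight: str = "inverse",
    decay_years: float = 2.0,
) -> float:
    """Weighted average of retrospective eGFR records.

    Weights decrease with the time between each record and the biosample
    date: ``inverse`` uses w = 1/(1 + dt) with dt in years, ``exponential``
    uses w = exp(-dt/decay_years).  A participant with no retrospective
    records has the historical eGFR imputed to the study-day eGFR.
    """
    dt = np.asarray(delta_years, dtype=float)
    vals = np.asarray(egfr_values, dtype=float)
    if dt.size == 0:
        return float(study_day_egfr)
    if np.any(dt < 0):
        raise ValueError("retrospective records must predate the study day")
    if weight == "inverse":
        w = 1.0 / (1.0 + dt)
    elif weight == "exponential":
        w = np.exp(-dt / decay_years)
    else:
        raise ValueError(f"unknown weight scheme {weight!r}")
    return float(np.sum(w * vals) / np.sum(w))


def final_egfr(
    days: Sequence[float],
    egfr_values: Sequence[float],
    rrt_start: Optional[float] = None,
    window_days: int = FINAL_WINDOW_DAYS,
) -> float:
    """Median eGFR over the last 6 months (182 days) of follow-up.

    ``days`` are times of the prospective readings (any consistent day
    scale).  If RRT was initiated, readings after ``rrt_start`` are censored
    and a reading of 10 is recorded at RRT start.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(egfr_values, dtype=float)
    order = np.argsort(d, kind="stable")
    d, v = d[order], v[order]
    if rrt_start is not None:
        keep = d < rrt_start
        d = np.append(d[keep], rrt_start)
        v = np.append(v[keep], RRT_EGFR)
    if d.size == 0:
        raise ValueError("no prospective eGFR readings and no RRT")
    last = d[-1]
    in_window = d >= last - window_days
    return float(np.median(v[in_window]))


def egfr_slope(years: Sequence[float], egfr_values: Sequence[float]) -> Optional[float]:
    """OLS slope of eGFR on time in years; None if fewer than 2 distinct times."""
    t = np.asarray(years, dtype=float)
    v = np.asarray(egfr_values, dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        return None
    tc = t - t.mean()
    return float(np.sum(tc * (v - v.mean())) / np.sum(tc * tc))


def progression_flags(study_day_egfr: float, final: float, thresholds=(30.0, 45.0)):
    """Progression to below each threshold; undefined (None) if already below
    the threshold at study day."""
    out = {}
    for thr in thresholds:
        if study_day_egfr < thr:
            out[thr] = None
        else:
            out[thr] = bool(final < thr)
    return out


def acr_category(acr: float) -> str:
    """Albuminuria category of one ACR reading (mg/mmol).

    Bands: [0, 3.39) normo, [3.39, 33.9] micro, (33.9, inf) macro; the
    boundary values resolve to the micro band.
    """
    if acr < 0:
        raise ValueError("ACR must be non-negative")
    if acr < ACR_MICRO:
        return "normo"
    if acr <= ACR_MACRO:
        return "micro"
    return "macro"


_STAGE_ORDER = {"normo": 0, "micro": 1, "macro": 2}


@dataclass
class StageEpisode:
    """A durable albuminuric stage starting at ``day``."""

    day: float
    stage: str


def durable_stages(days: Sequence[float], acrs: Sequence[float],
                   window: float = DURABILITY_DAYS) -> list[StageEpisode]:
    """Reduce an ACR series to durable stage episodes.

    A transition to a new stage is discarded as transient if a measurement of
    the prior stage occurs within ``window`` days before or after it, so
    isolated excursions (e.g. normo -> micro -> normo within 90 days) never
    change the standing stage.
    """
    d = np.asarray(days, dtype=float)
    a = np.asarray(acrs, dtype=float)
    order = np.argsort(d, kind="stable")
    d, a = d[order], a[order]
    cats = [acr_category(x) for x in a]
    episodes: list[StageEpisode] = []
    if len(cats) == 0:
        return episodes
    current = cats[0]
    episodes.append(StageEpisode(float(d[0]), current))
    for i in range(1, len(cats)):
        if cats[i] == current:
            continue
        nearby = np.abs(d - d[i]) <= window
        contradicted = any(cats[j] == current and nearby[j] and j != i for j in range(len(cats)))
        if contradicted:
            continue
        current = cats[i]
        episodes.append(StageEpisode(float(d[i]), current))
    return episodes


def albuminuria_status(days: Sequence[float], acrs: Sequence[float],
                       query_day: float) -> str:
    """Albuminuric status at ``query_day`` (typically the biosample date).

    Uses the two-out-of-three rule on the last three measurements on or
    before the query day; when no two of those three agree, falls back to the
    most recent durable stage (90-day transience rule).
    """
    d = np.asarray(days, dtype=float)
    a = np.asarray(acrs, dtype=float)
    mask = d <= query_day
    if not np.any(mask):
        raise ValueError("no ACR measurements before the query day")
    d_pre, a_pre = d[mask], a[mask]
    order = np.argsort(d_pre, kind="stable")
    d_pre, a_pre = d_pre[order], a_pre[order]
    last3 = [acr_category(x) for x in a_pre[-3:]]
    for stage in ("macro", "micro", "normo"):
        if last3.count(stage) >= 2:
            return stage
    episodes = durable_stages(d_pre, a_pre)
    return episodes[-1].stage


def incident_albuminuria(days: Sequence[float], acrs: Sequence[float],
                         study_day: float, baseline_status: str = "normo") -> bool:
    """Whether a durable micro/macro stage begins after the study day.

    Defined only for participants normoalbuminuric at baseline.
    """
    if baseline_status != "normo":
        raise ValueError("incident albuminuria is defined for baseline normoalbuminuria")
    for ep in durable_stages(days, acrs):
        if ep.day > study_day and ep.stage in ("micro", "macro"):
            return True
    return False


def derive_phenotypes(participants: Iterable, weight: str = "inverse") -> pd.DataFrame:
    """Derive the per-participant renal phenotypes from longitudinal records.

    ``participants`` are records with the layout produced by
    :mod:`renalpanel.simulate` (dated creatinine series with in-hospital
    flags, dated ACR series, sex/age, optional RRT start).  In-hospital
    creatinine readings are excluded before any derivation.

    Returns one row per participant with: study-day eGFR, weighted historical
    eGFR, final eGFR, prospective slope, follow-up length, record counts,
    progression flags (to <30 and <45; NaN when undefined), baseline
    albuminuric status and incident albuminuria.
    """
    rows = []
    for p in participants:
        cre = [(day, val, hosp) for (day, val, hosp) in p.creatinine_series if not hosp]
        days = np.array([c[0] for c in cre], dtype=float)
        vals = np.array([c[1] for c in cre], dtype=float)
        age_at = p.age + days / 365.25
        egfr = ckd_epi_egfr(vals, age_at, [p.sex] * len(vals), unit=p.creatinine_unit)
        egfr = np.atleast_1d(egfr)

        retro = days <= 0
        prosp = days > 0
        i_study = int(np.argmin(np.abs(days)))
        study_egfr = float(egfr[i_study])

        hist = weighted_historical_egfr(
            -days[retro & (days < 0)] / 365.25, egfr[retro & (days < 0)],
            study_egfr, weight=weight)

        rrt_day = p.rrt_day
        if np.any(prosp) or rrt_day is not None:
            fin = final_egfr(days[prosp], egfr[prosp], rrt_start=rrt_day)
        else:
            fin = np.nan
        if rrt_day is not None:
            pd_days = np.append(days[prosp & (days < rrt_day)], rrt_day)
            pd_vals = np.append(egfr[prosp & (days < rrt_day)], RRT_EGFR)
        else:
            pd_days, pd_vals = days[prosp], egfr[prosp]
        slope = egfr_slope(pd_days / 365.25, pd_vals)
        followup = float(pd_days.max() / 365.25) if pd_days.size else 0.0

        flags = progression_flags(study_egfr, fin) if np.isfinite(fin) else {30.0: None, 45.0: None}

        acr_days = np.array([x[0] for x in p.acr_series], dtype=float)
        acr_vals = np.array([x[1] for x in p.acr_series], dtype=float)
        if np.any(acr_days <= 0):
            base_status = albuminuria_status(acr_days, acr_vals, 0.0)
        else:
            base_status = None
        if base_status == "normo":
            incident = incident_albuminuria(acr_days, acr_vals, 0.0)
        else:
            incident = None

        rows.append({
            "id": p.id,
            "study_day_egfr": study_egfr,
            "weighted_historical_egfr": hist,
            "final_egfr": fin,
            "prospective_slope": np.nan if slope is None else slope,
            "followup_years": followup,
            "n_retro": int(np.sum(retro)),
            "n_prosp": int(np.sum(prosp)),
            "progressed_lt30": _flag(flags[30.0]),
            "progressed_lt45": _flag(flags[45.0]),
            "albuminuric_status": base_status,
            "incident_albuminuria": _flag(incident),
        })
    return pd.DataFrame(rows).set_index("id")


def _flag(x):
    return np.nan if x is None else float(x)


def progression_rate(flags: Sequence[float]):
    """Events, participants at risk and the percentage (1 d.p.) from a column
    of progression flags (1/0 with NaN for those already below threshold)."""
    f = np.asarray(flags, dtype=float)
    at_risk = np.isfinite(f)
    n_events = int(np.nansum(f))
    n_at_risk = int(at_risk.sum())
    pct = round(100.0 * n_events / n_at_risk, 1) if n_at_risk else float("nan")
    return n_events, n_at_risk, pct
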