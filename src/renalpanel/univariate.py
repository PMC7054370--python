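"""Per-biomarker association models.

Each biomarker is evaluated independently in a linear model for final eGFR
or a logistic model for progression, adjusted for one of three covariate
sets (basic; basic + ACR; full).  Inputs are expected Gaussianised and
standardized so coefficients read as effect per SD of Gaussianised
biomarker.  Significance is declared at the Bonferroni-corrected threshold
0.05/m for m biomarkers tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

BASIC = ["age", "sex", "diabetes_duration", "study_day_egfr", "followup_years"]
BASIC_ACR = BASIC + ["acr"]
FULL = BASIC_ACR + ["bmi", "dbp", "sbp", "hba1c", "hdl", "total_chol",
                    "ever_smoker", "weighted_historical_egfr"]

COVARIATE_SETS = {"basic": BASIC, "basic_acr": BASIC_ACR, "full": FULL}

ALPHA = 0.05


def bonferroni_threshold(n_tests: int) -> float:
    """Family-wise significance threshold 0.05/m."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return ALPHA / n_tests


@dataclass
class AssociationResult:
    biomarker: str
    outcome: str
    covariate_set: str
    family: str
    beta: float
    ci95: tuple
    p_value: float
    significant: bool
    n: int
    n_events: Optional[int] = None
    converged: bool = True
    unstable: bool = False


def fit_univariate(data: pd.DataFrame, biomarker: str, outcome: str,
                   covariate_set: str = "basic", family: str = "linear",
                   n_tests: int = 22, extra_covariates=()) -> AssociationResult:
    """Single-biomarker regression adjusted for a covariate set.

    ``data`` holds the (Gaussianised) biomarker, the outcome, and the
    covariates by name.  Complete-case analysis on all model columns.  Wald
    confidence interval and p-value for the biomarker coefficient;
    significance at 0.05/n_tests.  Logistic fits with fewer than 10 events
    are flagged unstable.
    """
    if covariate_set is None:
        covs = []
        covariate_set = "none"
    elif covariate_set in COVARIATE_SETS:
        covs = COVARIATE_SETS[covariate_set]
    else:
        raise ValueError(f"unknown covariate set {covariate_set!r}")
    cols = [outcome, biomarker] + covs + list(extra_covariates)
    d = data[cols].dropna()
    X = sm.add_constant(d[cols[1:]].astype(float))
    y = d[outcome].astype(float)

    n_events = None
    converged, unstable = True, False
    if family == "linear":
        res = sm.OLS(y, X).fit()
    elif family == "logistic":
        n_events = int(y.sum())
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            converged = bool(res.converged)
        except Exception:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=200, method="bfgs")
            converged = False
        if n_events < 10 or min(n_events, len(y) - n_events) < 10:
            unstable = True
        if np.abs(res.params[biomarker]) > 15:  # quasi-separation
            converged = False
    else:
        raise ValueError(f"unknown family {family!r}")

    beta = float(res.params[biomarker])
    ci = res.conf_int().loc[biomarker]
    p = float(res.pvalues[biomarker])
    thr = bonferroni_threshold(n_tests)
    return AssociationResult(
        biomarker=biomarker, outcome=outcome, covariate_set=covariate_set,
        family=family, beta=beta, ci95=(float(ci[0]), float(ci[1])),
        p_value=p, significant=bool(p < thr), n=len(y), n_events=n_events,
        converged=converged, unstable=unstable)


def stratified_rerun(data: pd.DataFrame, stratum: str, biomarker: str,
                     outcome: str, covariate_set: str = "basic",
                     family: str = "linear", n_tests: int = 22) -> AssociationResult:
    """Refit the same model on a phenotype-defined stratum.

    Strata: ``normo`` (normoalbuminuric at baseline), ``normo_micro``,
    ``macro``, ``egfr_ge90``.  Logistic results on strata with fewer than 10
    events are flagged unstable.
    """
    if stratum == "all":
        sub = data
    elif stratum == "normo":
        sub = data[data["albuminuric_status"] == "normo"]
    elif stratum == "normo_micro":
        sub = data[data["albuminuric_status"].isin(["normo", "micro"])]
    elif stratum == "macro":
        sub = data[data["albuminuric_status"] == "macro"]
    elif stratum == "egfr_ge90":
        sub = data[data["study_day_egfr"] >= 90]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    if len(sub) == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    return fit_univariate(sub, biomarker, outcome, covariate_set, family, n_tests)


def univariate_table(data: pd.DataFrame, biomarkers, outcome: str,
                     family: str = "linear",
                     covariate_sets=("basic", "basic_acr", "full")) -> pd.DataFrame:
    """Biomarker x covariate-set grid of beta (95% CI) and p, one row per
    biomarker, shaped like the published association tables."""
    rows = []
    m = len(biomarkers)
    for bio in biomarkers:
        row = {"biomarker": bio}
        for cs in covariate_sets:
            r = fit_univariate(data, bio, outcome, cs, family, n_tests=m)
            row[f"beta_{cs}"] = r.beta
            row[f"ci_{cs}"] = f"({r.ci95[0]:.2f}, {r.ci95[1]:.2f})"
            row[f"p_{cs}"] = r.p_value
            row[f"significant_{cs}"] = r.significant
        rows.append(row)
    return pd.DataFrame(rows).set_index("biomarker")
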