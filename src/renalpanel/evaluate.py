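"""Cross-validated model evaluation.

Tenfold cross-validation with per-observation test log-likelihoods, and the
discrimination metrics reported for the panel models: test-set difference in
log-likelihood (nats) against a covariate-only reference, squared Pearson
correlation between observed and predicted outcome, AUC via the
Mann-Whitney rank identity, and the expected information for discrimination
Lambda in bits (mean weight of evidence in cases and against controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .horseshoe import ShrinkagePrior, fit_shrinkage, posterior_predict, pointwise_loglik


def make_folds(n: int, k: int = 10, seed: int = 0, stratify=None) -> np.ndarray:
    """Fold assignment (0..k-1) per observation; stratified by event status
    when ``stratify`` (a binary vector) is given, so rare events spread
    across folds."""
    if n < k:
        raise ValueError("need at least k observations")
    idx = np.arange(n)
    folds = np.empty(n, dtype=int)
    if stratify is not None:
        s = np.asarray(stratify).astype(int)
        if s.min() == s.max():
            raise ValueError("stratification requires both classes present")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(idx, s)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(idx)
    for f, (_, test) in enumerate(it):
        folds[test] = f
    return folds


def crossvalidate(X_cov, X_bio, y, family: str = "linear",
                  prior: Optional[ShrinkagePrior] = None, k: int = 10,
                  seed: int = 0, folds: Optional[np.ndarray] = None,
                  pred_draws: int = 200):
    """K-fold cross-validation of the shrinkage model.

    Refits on each training split and collects, in the original observation
    order: posterior-mean test predictions, a thinned matrix of per-draw
    test predictions (for uncertainty intervals on metrics), and pointwise
    test log-likelihoods.  Binary outcomes use event-stratified folds.
    """
    X_cov = np.asarray(X_cov, dtype=float)
    X_bio = (np.asarray(X_bio, dtype=float) if X_bio is not None
             else np.empty((X_cov.shape[0], 0)))
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds is None:
        strat = y if family == "logistic" else None
        folds = make_folds(n, k, seed, stratify=strat)
    k = int(folds.max()) + 1

    pred_mean = np.empty(n)
    lppd = np.empty(n)
    draw_preds = None
    rng = np.random.default_rng(seed)
    for f in range(k):
        test = folds == f
        train = ~test
        if family == "logistic" and y[test].sum() == 0:
            # a fold without events still gets predictions; reported upstream
            pass
        fit = fit_shrinkage(X_cov[train], X_bio[train], y[train], family,
                            prior, seed=seed * 1009 + f)
        preds = posterior_predict(fit, X_cov[test], X_bio[test])
        pred_mean[test] = preds.mean(axis=0)
        lppd[test] = pointwise_loglik(fit, X_cov[test], X_bio[test], y[test])
        if draw_preds is None:
            n_thin = min(pred_draws, preds.shape[0])
            thin_idx = np.sort(rng.choice(preds.shape[0], n_thin, replace=False))
            draw_preds = np.empty((n_thin, n))
        draw_preds[:, test] = preds[thin_idx]
    return {"pred_mean": pred_mean, "pred_draws": draw_preds, "lppd": lppd,
            "folds": folds}


def delta_loglik(lppd_model, lppd_reference, folds_model=None,
                 folds_reference=None) -> float:
    """Summed out-of-fold log-likelihood difference (nats) between a model
    and a reference evaluated on the same observations and folds."""
    a = np.asarray(lppd_model, dtype=float)
    b = np.asarray(lppd_reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("models were evaluated on different observations")
    if folds_model is not None and folds_reference is not None:
        if not np.array_equal(folds_model, folds_reference):
            raise ValueError("fold assignments differ between models")
    return float(np.sum(a) - np.sum(b))


def cv_r2(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted outcome."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.std() == 0 or p.std() == 0:
        raise ValueError("zero variance in observed or predicted values")
    return float(np.corrcoef(o, p)[0, 1] ** 2)


def auroc(labels, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic: the probability that
    a random case outscores a random control, ties counting one half."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def expected_info_discrimination(labels, probs, prior: Optional[float] = None,
                                 eps: float = 1e-6, clip: bool = True) -> float:
    """Expected information for discrimination, Lambda, in bits.

    Per-observation weight of evidence
    ``W_i = log2( p_i/(1-p_i) * (1-pi)/pi )`` against the prior odds
    (``pi`` defaults to the observed event fraction);
    ``Lambda = (mean(W | cases) + mean(-W | controls)) / 2``.
    This is the plug-in (empirical mean) estimator.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    if prior is None:
        prior = float(y.mean())
    if not (0 < prior < 1):
        raise ValueError("prior must be in (0, 1)")
    if clip:
        p = np.clip(p, eps, 1 - eps)
    elif np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must be in (0, 1); enable clipping")
    w = np.log2(p / (1 - p)) - np.log2(prior / (1 - prior))
    return float(0.5 * (w[y == 1].mean() - w[y == 0].mean()))


@dataclass
class CVReport:
    """Cross-validated performance of one model against a reference."""

    label: str
    covariate_set: str
    family: str
    n: int
    n_events: Optional[int]
    delta_loglik: float
    r2: Optional[float] = None
    r2_interval: Optional[tuple] = None
    auc: Optional[float] = None
    auc_interval: Optional[tuple] = None
    lambda_bits: Optional[float] = None
    lambda_gain_bits: Optional[float] = None
    folds: np.ndarray = field(default=None, repr=False)


def cv_report(label, covariate_set, family, y, cv_model, cv_reference) -> CVReport:
    """Assemble the table-shaped summary for one model/reference pair.

    Linear outcomes report r-squared with a 95% uncertainty interval across
    posterior-draw predictions; binary outcomes report AUC (with interval),
    Lambda, and the Lambda gain over the reference on the same folds.
    """
    y = np.asarray(y, dtype=float)
    dll = delta_loglik(cv_model["lppd"], cv_reference["lppd"],
                       cv_model["folds"], cv_reference["folds"])
    rep = CVReport(label=label, covariate_set=covariate_set, family=family,
                   n=len(y), n_events=int(y.sum()) if family == "logistic" else None,
                   delta_loglik=dll, folds=cv_model["folds"])
    draws = cv_model["pred_draws"]
    if family == "linear":
        rep.r2 = cv_r2(y, cv_model["pred_mean"])
        per_draw = np.array([cv_r2(y, d) for d in draws])
        rep.r2_interval = tuple(np.percentile(per_draw, [2.5, 97.5]))
    else:
        rep.auc = auroc(y, cv_model["pred_mean"])
        per_draw = np.array([auroc(y, d) for d in draws])
        rep.auc_interval = tuple(np.percentile(per_draw, [2.5, 97.5]))
        rep.lambda_bits = expected_info_discrimination(y, cv_model["pred_mean"])
        ref_lambda = expected_info_discrimination(y, cv_reference["pred_mean"])
        rep.lambda_gain_bits = rep.lambda_bits - ref_lambda
    return rep
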