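"""Projection predictive variable selection.

Posterior draws of the full model (all biomarkers, regularised horseshoe)
are projected onto sparse submodels that keep the clinical covariates and a
subset of biomarkers.  The discrepancy between the full and projected
predictive distributions is the Kullback-Leibler divergence, averaged over
observations and draws; forward selection adds at each step the biomarker
minimising it.  The relative explanatory power of a panel of size k is
1 - KL_k / KL_0, where KL_0 is the covariate-only projection, so the empty
panel scores 0 and the full panel scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .horseshoe import ShrinkageFit

IRLS_TOL = 1e-8
IRLS_MAXIT = 100


@dataclass
class SelectionPath:
    markers: list  # names (or indices) in selection order
    kl: list  # KL per panel size, starting at size 0 (covariates only)
    relative_power: list  # per panel size, aligned with kl
    treat_acr_as_biomarker: bool = False

    def table(self):
        import pandas as pd

        rows = [{"size": 0, "added": "", "kl_nats": self.kl[0],
                 "relative_power": self.relative_power[0]}]
        for i, name in enumerate(self.markers):
            rows.append({"size": i + 1, "added": name, "kl_nats": self.kl[i + 1],
                         "relative_power": self.relative_power[i + 1]})
        return pd.DataFrame(rows)


def _thin(fit: ShrinkageFit, n_draws: int, seed: int):
    S = fit.n_draws
    if n_draws >= S:
        return np.arange(S)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(S, n_draws, replace=False))


def project_submodel(fit: ShrinkageFit, subset, X_cov, X_bio,
                     n_draws: int = 400, seed: int = 0):
    """Project full-model draws onto the submodel keeping ``subset`` biomarkers.

    Returns ``(coefs, kl)``: per-draw projected coefficients (columns:
    intercept, covariates, subset biomarkers) and the KL divergence from the
    full to the projected predictive, averaged over observations and draws.

    Linear family: the projected coefficients are the least-squares fit of
    each draw's linear predictor onto the submodel design and the projected
    variance absorbs the discrepancy; logistic family: iteratively
    reweighted least squares matches the full model's fitted probabilities.
    """
    subset = np.asarray(sorted(subset), dtype=int)
    if subset.size and (subset.min() < 0 or subset.max() >= fit.n_bio):
        raise ValueError("subset indices out of range")
    X_cov = np.asarray(X_cov, dtype=float)
    X_bio = np.asarray(X_bio, dtype=float)
    n = X_cov.shape[0]
    D = np.column_stack([np.ones(n), X_cov, X_bio[:, subset]])
    idx = _thin(fit, n_draws, seed)

    F = (fit.alpha[idx, None] + fit.b[idx] @ X_cov.T
         + fit.beta[idx] @ X_bio.T)  # (S, n)

    if fit.family == "linear":
        q, r = np.linalg.qr(D)
        if np.linalg.matrix_rank(r) < D.shape[1]:
            raise np.linalg.LinAlgError("singular submodel design")
        coefs = np.linalg.solve(r, q.T @ F.T).T  # (S, q)
        resid = F - coefs @ D.T
        msd = np.mean(resid ** 2, axis=1)  # per draw
        sig2 = fit.sigma[idx] ** 2
        sig2_s = sig2 + msd
        # KL( N(f, sig2) || N(proj, sig2_s) ) averaged over observations
        kl_draw = (0.5 * np.log(sig2_s / sig2)[:, None]
                   + (sig2[:, None] + resid ** 2) / (2.0 * sig2_s[:, None])
                   - 0.5).mean(axis=1)
        return coefs, float(kl_draw.mean())

    P = expit(F)
    S = P.shape[0]
    q = D.shape[1]
    coefs = np.empty((S, q))
    kl_draw = np.empty(S)
    theta0 = np.zeros(q)
    for s in range(S):
        theta = _irls_fractional(D, P[s], theta0)
        coefs[s] = theta
        eta = D @ theta
        qs = expit(eta)
        qs = np.clip(qs, 1e-12, 1 - 1e-12)
        ps = np.clip(P[s], 1e-12, 1 - 1e-12)
        kl_draw[s] = np.mean(ps * np.log(ps / qs)
                             + (1 - ps) * np.log((1 - ps) / (1 - qs)))
        theta0 = theta  # warm start: consecutive draws are similar
    return coefs, float(kl_draw.mean())


def _irls_fractional(D, p_target, theta0):
    """Logistic projection: IRLS on fractional responses p_target."""
    theta = theta0.copy()
    for _ in range(IRLS_MAXIT):
        eta = D @ theta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (p_target - mu) / w
        wd = D * w[:, None]
        theta_new = np.linalg.solve(D.T @ wd, wd.T @ z)
        if np.max(np.abs(theta_new - theta)) < IRLS_TOL:
            return theta_new
        theta = theta_new
    return theta


def forward_select(fit: ShrinkageFit, X_cov, X_bio, max_size: int = None,
                   marker_names=None, n_draws: int = 400, seed: int = 0,
                   treat_acr_as_biomarker: bool = False) -> SelectionPath:
    """Greedy forward selection on projection KL.

    At each step the biomarker whose addition minimises the projected KL is
    added (ties broken by column order).  Returns the ordered path with KL
    and relative explanatory power per panel size.
    """
    p = fit.n_bio
    if max_size is None:
        max_size = p
    if not (1 <= max_size <= p):
        raise ValueError("max_size must be in [1, number of biomarkers]")
    names = list(marker_names) if marker_names is not None else list(range(p))

    _, kl0 = project_submodel(fit, [], X_cov, X_bio, n_draws, seed)
    selected: list[int] = []
    kl_path = [kl0]
    remaining = list(range(p))
    for _ in range(max_size):
        best_j, best_kl = None, np.inf
        for j in remaining:
            _, kl = project_submodel(fit, selected + [j], X_cov, X_bio,
                                     n_draws, seed)
            if kl < best_kl - 1e-15:
                best_j, best_kl = j, kl
        selected.append(best_j)
        remaining.remove(best_j)
        kl_path.append(best_kl)

    if kl0 <= 0:
        power = [1.0] * len(kl_path)
        power[0] = 0.0
    else:
        power = [1.0 - k / kl0 for k in kl_path]
        power[0] = 0.0
    return SelectionPath(markers=[names[j] for j in selected], kl=kl_path,
                         relative_power=power,
                         treat_acr_as_biomarker=treat_acr_as_biomarker)


def report_selection(path: SelectionPath, plot_path=None):
    """Selection path as a (size, added marker, KL, relative power) table;
    optionally writes the power-vs-panel-size curve as an SVG."""
    tab = path.table()
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(tab["size"], tab["relative_power"], marker="o")
        for _, row in tab.iterrows():
            if row["added"]:
                ax.annotate(str(row["added"]), (row["size"], row["relative_power"]),
                            textcoords="offset points", xytext=(4, -10), fontsize=7)
        ax.set_xlabel("panel size")
        ax.set_ylabel("relative explanatory power")
        ax.set_ylim(-0.02, 1.05)
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return tab
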