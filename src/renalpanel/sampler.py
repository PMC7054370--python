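"""No-U-Turn sampler (NUTS) with dual-averaging step-size adaptation.

A compact gradient-based MCMC engine used by the hierarchical-shrinkage
models: the Hoffman-Gelman tree-doubling scheme with slice sampling across
the trajectory, a diagonal mass matrix estimated during warmup, and
divergence tracking.  Models supply a single ``logp_grad(theta)`` callable
returning the joint log density (up to a constant) and its gradient in the
unconstrained parameterisation.
"""

from __future__ import annotations

import numpy as np

MAX_DELTA = 1000.0  # energy error beyond which a trajectory is divergent


def _leapfrog(logp_grad, theta, r, grad, eps, minv):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * minv * r1
    lp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, lp1, grad1


def _find_reasonable_epsilon(logp_grad, theta, minv, rng):
    eps = 1.0
    lp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.size) / np.sqrt(minv)
    h0 = lp - 0.5 * np.sum(minv * r * r)
    _, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, minv)
    h1 = lp1 - 0.5 * np.sum(minv * r1 * r1)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** a
        _, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, minv)
        h1 = lp1 - 0.5 * np.sum(minv * r1 * r1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * np.log(0.5):
            break
    return eps


class _Tree:
    __slots__ = ("theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
                 "theta_prop", "lp_prop", "grad_prop", "n_valid", "stop",
                 "diverged", "alpha", "n_alpha")


def _build_tree(logp_grad, theta, r, grad, log_u, v, depth, eps, h0, minv, rng):
    if depth == 0:
        theta1, r1, lp1, grad1 = _leapfrog(logp_grad, theta, r, grad, v * eps, minv)
        h1 = lp1 - 0.5 * np.sum(minv * r1 * r1)
        if not np.isfinite(h1):
            h1 = -np.inf
        t = _Tree()
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.r_m = t.r_p = r1
        t.grad_m = t.grad_p = t.grad_prop = grad1
        t.lp_prop = lp1
        t.n_valid = int(log_u <= h1)
        t.diverged = (log_u - MAX_DELTA) >= h1
        t.stop = t.diverged
        t.alpha = min(1.0, np.exp(min(h1 - h0, 0.0)))
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, theta, r, grad, log_u, v, depth - 1, eps, h0, minv, rng)
    if not t.stop:
        if v == -1:
            t2 = _build_tree(logp_grad, t.theta_m, t.r_m, t.grad_m, log_u, v,
                             depth - 1, eps, h0, minv, rng)
            t.theta_m, t.r_m, t.grad_m = t2.theta_m, t2.r_m, t2.grad_m
        else:
            t2 = _build_tree(logp_grad, t.theta_p, t.r_p, t.grad_p, log_u, v,
                             depth - 1, eps, h0, minv, rng)
            t.theta_p, t.r_p, t.grad_p = t2.theta_p, t2.r_p, t2.grad_p
        if t2.n_valid > 0 and rng.random() < t2.n_valid / max(t.n_valid + t2.n_valid, 1):
            t.theta_prop, t.lp_prop, t.grad_prop = t2.theta_prop, t2.lp_prop, t2.grad_prop
        t.n_valid += t2.n_valid
        t.diverged = t.diverged or t2.diverged
        t.stop = t2.stop or _uturn(t.theta_p, t.theta_m, t.r_p, t.r_m, minv)
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
    return t


def _uturn(theta_p, theta_m, r_p, r_m, minv):
    d = theta_p - theta_m
    return (d @ (minv * r_m) < 0) or (d @ (minv * r_p) < 0)


def nuts(logp_grad, init, n_warmup, n_draws, rng, target_accept=0.9,
         max_treedepth=10):
    """Sample one chain; returns (draws, stats).

    ``draws`` has shape (n_draws, dim).  ``stats`` reports divergences after
    warmup, the adapted step size, the diagonal inverse mass, and the mean
    acceptance statistic.
    """
    theta = np.array(init, dtype=float)
    dim = theta.size
    minv = np.ones(dim)

    draws = np.empty((n_draws, dim))
    divergences = 0
    accept_sum = 0.0

    # two warmup phases: step-size adaptation with unit mass, then mass
    # estimation from the first phase's second half and re-adaptation
    w1 = max(n_warmup // 2, 20)
    w2 = max(n_warmup - w1, 20)
    phase1 = np.empty((w1, dim))

    for phase, n_iter in ((1, w1), (2, w2), (3, n_draws)):
        if phase == 2:
            tail = phase1[w1 // 2:]
            var = tail.var(axis=0)
            n_tail = tail.shape[0]
            minv = (n_tail * var + 5.0 * 1e-3) / (n_tail + 5.0)
            minv = np.maximum(minv, 1e-8)
        if phase in (1, 2):
            eps = _find_reasonable_epsilon(logp_grad, theta, minv, rng)
            mu = np.log(10.0 * eps)
            log_eps_bar, h_bar = 0.0, 0.0
            gamma, t0, kappa = 0.05, 10.0, 0.75
        else:
            eps = np.exp(log_eps_bar)

        lp, grad = logp_grad(theta)
        for m in range(n_iter):
            r0 = rng.standard_normal(dim) / np.sqrt(minv)
            h0 = lp - 0.5 * np.sum(minv * r0 * r0)
            log_u = h0 + np.log(rng.random())
            theta_m = theta_p = theta
            r_m = r_p = r0
            grad_m = grad_p = grad
            n_valid, stop, depth = 1, False, 0
            alpha, n_alpha = 0.0, 1
            while not stop and depth < max_treedepth:
                v = 1 if rng.random() < 0.5 else -1
                if v == -1:
                    t = _build_tree(logp_grad, theta_m, r_m, grad_m, log_u, v,
                                    depth, eps, h0, minv, rng)
                    theta_m, r_m, grad_m = t.theta_m, t.r_m, t.grad_m
                else:
                    t = _build_tree(logp_grad, theta_p, r_p, grad_p, log_u, v,
                                    depth, eps, h0, minv, rng)
                    theta_p, r_p, grad_p = t.theta_p, t.r_p, t.grad_p
                if not t.stop and t.n_valid > 0 and rng.random() < t.n_valid / n_valid:
                    theta, lp, grad = t.theta_prop, t.lp_prop, t.grad_prop
                n_valid += t.n_valid
                alpha, n_alpha = t.alpha, t.n_alpha
                stop = t.stop or _uturn(theta_p, theta_m, r_p, r_m, minv)
                if t.diverged:
                    if phase == 3:
                        divergences += 1
                    break
                depth += 1

            if phase in (1, 2):
                frac = 1.0 / (m + 1 + t0)
                h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha / n_alpha)
                log_eps = mu - np.sqrt(m + 1) / gamma * h_bar
                w = (m + 1) ** -kappa
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = np.exp(log_eps)
                if phase == 1:
                    phase1[m] = theta
            else:
                draws[m] = theta
                accept_sum += alpha / n_alpha

    stats = {
        "divergences": divergences,
        "step_size": float(np.exp(log_eps_bar)),
        "inv_mass": minv.copy(),
        "mean_accept": accept_sum / max(n_draws, 1),
    }
    return draws, stats
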