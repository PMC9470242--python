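"""Adaptive Hamiltonian Monte Carlo.

A compact HMC implementation used to sample the hierarchical posterior:
jittered trajectory lengths, dual-averaging step-size adaptation, and
diagonal mass-matrix estimation during warmup.  Target densities supply a
fused (log p, grad log p) callable over an unconstrained parameter vector.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hmc_sample"]


def _find_initial_step(logp_grad, x0, rng, inv_mass):
    """Double/halve the step until one leapfrog step crosses 50% acceptance."""
    eps = 0.1 / max(1.0, x0.size ** 0.25)
    lp0, g0 = logp_grad(x0)
    p = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p * p)

    def one_step(eps):
        p1 = p + 0.5 * eps * g0
        x1 = x0 + eps * inv_mass * p1
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        return lp1 - 0.5 * np.sum(inv_mass * p1 * p1)

    h1 = one_step(eps)
    if not np.isfinite(h1):
        direction = -1
    else:
        direction = 1 if (h1 - h0) > np.log(0.5) else -1
    for _ in range(30):
        eps *= 2.0 ** direction
        h1 = one_step(eps)
        ok = np.isfinite(h1) and (h1 - h0) > np.log(0.5)
        if (direction == 1) != ok:
            break
    return max(eps, 1e-8)


def _python_trajectory(logp_grad):
    """Default leapfrog integrator built on the (log p, grad) callable."""

    def traj(x, p, g, eps, n_leap, inv_mass):
        x, p, g = x.copy(), p.copy(), g.copy()
        lp = -np.inf
        for _ in range(n_leap):
            p = p + 0.5 * eps * g
            x = x + eps * inv_mass * p
            lp, g = logp_grad(x)
            if not np.isfinite(lp):
                return x, p, -np.inf, g, False
            p = p + 0.5 * eps * g
        return x, p, lp, g, True

    return traj


def hmc_sample(logp_grad, x0, n_warmup: int, n_samples: int, rng,
               target_accept: float = 0.85, max_leapfrog: int = 24,
               trajectory=None):
    """Run one HMC chain; returns (draws, info).

    draws has shape (n_samples, dim).  info carries acceptance rate,
    divergence count, final step size and the diagonal inverse mass.
    Warmup adapts the step size by dual averaging throughout and re-estimates
    a diagonal mass matrix at the end of two expanding windows.  ``trajectory``
    may supply a fused integrator with signature
    (x, p, grad, eps, n_leap, inv_mass) -> (x, p, lp, grad, ok).
    """
    if trajectory is None:
        trajectory = _python_trajectory(logp_grad)
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    # Stan-style windowing: init buffer (step only), doubling mass windows,
    # terminal buffer (step only)
    init_buf = min(max(40, int(0.12 * n_warmup)), n_warmup // 3)
    term_buf = min(max(50, int(0.12 * n_warmup)), n_warmup // 3)
    updates = []
    w, size = init_buf, 25
    while w + size < n_warmup - term_buf:
        nxt = w + size
        if nxt + 2 * size >= n_warmup - term_buf:
            nxt = n_warmup - term_buf
        updates.append(nxt)
        w, size = nxt, 2 * size
    updates = set(updates)
    window_draws = []

    draws = np.empty((n_samples, dim))
    n_div = 0
    n_acc = 0.0
    total = n_warmup + n_samples

    for it in range(total):
        warming = it < n_warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p * p)
        n_leap = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
        x_new, p_new, lp_new, g_new, ok = trajectory(x, p, grad, eps, n_leap, inv_mass)
        diverged = not ok
        if diverged:
            accept_prob = 0.0
        else:
            h1 = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
            dh = h1 - h0
            if dh < -1000.0:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = min(1.0, np.exp(min(dh, 0.0)))
        if diverged and not warming:
            n_div += 1
        if accept_prob > 0 and rng.random() < accept_prob:
            x, lp, grad = x_new, lp_new, g_new

        if warming:
            adapt_iter += 1
            h_bar = (1 - 1 / (adapt_iter + t0)) * h_bar + (target_accept - accept_prob) / (adapt_iter + t0)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if it >= init_buf:
                window_draws.append(x.copy())
            if it in updates and len(window_draws) > 10:
                arr = np.asarray(window_draws)
                old = inv_mass
                var = np.var(arr, axis=0)
                n = arr.shape[0]
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-8)
                window_draws = []
                # keep the step size continuous under the metric change and
                # restart dual averaging around it
                eps = eps * float(np.sqrt(np.median(old / inv_mass)))
                eps = min(max(eps, 1e-8), 10.0)
                mu = np.log(10.0 * eps)
                h_bar, log_eps_bar, adapt_iter = 0.0, np.log(eps), 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            n_acc += accept_prob
            draws[it - n_warmup] = x

    info = {"accept_rate": n_acc / max(n_samples, 1), "divergences": n_div,
            "step_size": float(eps), "inv_mass": inv_mass}
    return draws, info

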