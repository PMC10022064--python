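"""Adaptive Hamiltonian Monte Carlo for smooth log posteriors.

A compact HMC engine used by the spatial module: leapfrog integration with a
diagonal mass matrix adapted during warmup (Welford estimates over two
windows) and step size tuned by Nesterov dual averaging toward a target
acceptance rate.  The number of leapfrog steps is jittered uniformly to avoid
resonance.  Works on any function returning (log density, gradient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

_DIVERGENCE = 1000.0  # energy error treated as a divergent trajectory


@dataclass
class SampleStats:
    accept_rate: np.ndarray      # per chain
    step_size: np.ndarray        # per chain, post-adaptation
    divergences: np.ndarray      # per chain


def _leapfrog(q, p, grad, eps, n_steps, logp_grad, minv):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * minv * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, lp, grad
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def _find_initial_step(q, lp, grad, logp_grad, minv, rng):
    # overflow in trial energies is expected and handled via -inf
    np.seterr(over="ignore", invalid="ignore")
    eps = 0.1
    p = rng.standard_normal(q.size) / np.sqrt(minv)
    h0 = lp - 0.5 * float(p * minv @ p)
    q1, p1, lp1, _ = _leapfrog(q, p, grad, eps, 1, logp_grad, minv)
    h1 = lp1 - 0.5 * float(p1 * minv @ p1) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        q1, p1, lp1, _ = _leapfrog(q, p, grad, eps, 1, logp_grad, minv)
        h1 = lp1 - 0.5 * float(p1 * minv @ p1) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


def sample_hmc(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    n_warmup: int = 500,
    n_draws: int = 500,
    n_chains: int = 4,
    seed: int = 0,
    target_accept: float = 0.8,
    n_leapfrog: tuple[int, int] = (8, 24),
    init_jitter: float | np.ndarray = 0.5,
) -> tuple[np.ndarray, SampleStats]:
    """Draw from a log density; returns (chains, draws, dim) and stats.

    Chains are seeded independently from ``seed``; warmup draws are discarded.
    """
    dim = init.size
    draws = np.empty((n_chains, n_draws, dim))
    accept = np.zeros(n_chains)
    stepsizes = np.zeros(n_chains)
    divergences = np.zeros(n_chains, dtype=int)
    # mass-update points within warmup (fractions of the warmup run)
    w1, w2 = int(0.4 * n_warmup), int(0.8 * n_warmup)

    err_state = np.seterr(over="ignore", invalid="ignore")
    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        q = init + np.asarray(init_jitter) * rng.standard_normal(dim)
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            q = init.copy()
            lp, grad = logp_grad(q)
        minv = np.ones(dim)  # inverse mass (posterior variance estimate)
        eps = _find_initial_step(q, lp, grad, logp_grad, minv, rng)
        # dual averaging state
        mu, log_eps_bar, h_bar = np.log(10 * eps), 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        da_m = 0  # dual-averaging iteration counter, restarted on metric change
        welford_n, welford_m, welford_s = 0, np.zeros(dim), np.zeros(dim)
        n_acc = 0

        for it in range(n_warmup + n_draws):
            adapting = it < n_warmup
            p = rng.standard_normal(dim) / np.sqrt(minv)
            h0 = lp - 0.5 * float((p * minv) @ p)
            L = int(rng.integers(n_leapfrog[0], n_leapfrog[1] + 1))
            q1, p1, lp1, grad1 = _leapfrog(q, p, grad, eps, L, logp_grad, minv)
            if np.isfinite(lp1):
                h1 = lp1 - 0.5 * float((p1 * minv) @ p1)
                delta = h1 - h0
            else:
                delta = -np.inf
            alpha = min(1.0, np.exp(min(delta, 0.0)))
            if delta < -_DIVERGENCE:
                divergences[chain] += 1
            if np.log(rng.uniform()) < delta:
                q, lp, grad = q1, lp1, grad1
                if not adapting:
                    n_acc += 1
            if adapting:
                da_m += 1
                h_bar = (1 - 1 / (da_m + t0)) * h_bar \
                    + (target_accept - alpha) / (da_m + t0)
                log_eps = mu - np.sqrt(da_m) / gamma * h_bar
                log_eps_bar = da_m ** -kappa * log_eps \
                    + (1 - da_m ** -kappa) * log_eps_bar
                eps = float(np.exp(log_eps))
                if w1 <= it < w2:
                    welford_n += 1
                    d = q - welford_m
                    welford_m += d / welford_n
                    welford_s += d * (q - welford_m)
                if it == w2 - 1 and welford_n > 10:
                    var = welford_s / (welford_n - 1)
                    minv = np.clip(var, 1e-8, None)
                    # re-tune the step size for the new metric
                    eps = _find_initial_step(q, lp, grad, logp_grad, minv, rng)
                    mu, log_eps_bar, h_bar, da_m = np.log(10 * eps), 0.0, 0.0, 0
                if it == n_warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            else:
                draws[chain, it - n_warmup] = q
        accept[chain] = n_acc / n_draws
        stepsizes[chain] = eps
        if accept[chain] < 0.5:
            logger.warning("chain %d acceptance rate %.2f is low", chain, accept[chain])

    np.seterr(**err_state)
    return draws, SampleStats(accept_rate=accept, step_size=stepsizes,
                              divergences=divergences)
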