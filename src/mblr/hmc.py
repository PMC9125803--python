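"""A compact Hamiltonian Monte Carlo sampler with warmup adaptation.

Implements the standard recipe: leapfrog integration with a diagonal mass
matrix, dual-averaging step-size adaptation toward a target acceptance rate,
and a single mass-matrix re-estimation window during warmup.  Trajectory
lengths are jittered to avoid resonance.  This is deliberately plain HMC (not
NUTS): the posteriors in this package are small and smooth, and a fixed
trajectory length with jitter mixes well while keeping the per-iteration cost
predictable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ChainResult", "sample_chain"]

_DIVERGENCE_THRESHOLD = 1000.0  # energy error treated as a divergent transition


@dataclass
class ChainResult:
    positions: np.ndarray  # (kept_draws, dim), post-warmup only
    accept_prob: np.ndarray  # (kept_draws,)
    divergent: np.ndarray  # (kept_draws,) bool
    step_size: float
    inv_mass: np.ndarray


def _find_initial_step_size(logp_grad, q, inv_mass, rng) -> float:
    """Stan-style heuristic: double/halve until the one-step acceptance crosses 0.5."""
    eps = 1.0
    logp0, grad0 = logp_grad(q)
    p = rng.normal(size=q.shape) / np.sqrt(inv_mass)

    def joint(eps):
        with np.errstate(over="ignore", invalid="ignore"):
            p1 = p + 0.5 * eps * grad0
            q1 = q + eps * inv_mass * p1
            logp1, grad1 = logp_grad(q1)
            if not np.isfinite(logp1):
                return -np.inf
            p1 = p1 + 0.5 * eps * grad1
            h0 = logp0 - 0.5 * np.sum(inv_mass * p * p)
            h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        delta = h1 - h0
        return delta if np.isfinite(delta) else -np.inf

    delta = joint(eps)
    direction = 1 if delta > np.log(0.5) else -1
    for _ in range(50):
        eps = eps * (2.0**direction)
        delta = joint(eps)
        if not np.isfinite(delta):
            delta = -np.inf
        if (direction == 1 and delta <= np.log(0.5)) or (direction == -1 and delta >= np.log(0.5)):
            break
    return max(eps, 1e-8)


def _leapfrog(logp_grad, q, p, grad, eps, n_steps, inv_mass):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        logp, grad = logp_grad(q)
        if not np.isfinite(logp):
            return q, p, logp, grad
        if step != n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def sample_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_iterations: int,
    n_warmup: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.8,
    trajectory_length: float = 1.2,
    max_leapfrog: int = 48,
) -> ChainResult:
    """Run one HMC chain; returns only post-warmup draws."""
    if n_iterations <= n_warmup:
        raise ValueError("iterations must exceed warmup")
    q = np.asarray(q0, dtype=float).copy()
    dim = q.size
    inv_mass = np.ones(dim)

    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial position has non-finite log density")

    eps = _find_initial_step_size(logp_grad, q, inv_mass, rng)

    # dual averaging state (Hoffman & Gelman 2014 defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # mass adaptation window: draws from [w_lo, w_hi) estimate the variances
    w_lo = int(0.25 * n_warmup)
    w_hi = int(0.75 * n_warmup)
    window: list[np.ndarray] = []

    kept = n_iterations - n_warmup
    positions = np.empty((kept, dim))
    accept_probs = np.empty(kept)
    divergent = np.zeros(kept, dtype=bool)

    for it in range(n_iterations):
        warming = it < n_warmup
        p0 = rng.normal(size=dim) / np.sqrt(inv_mass)
        n_steps = int(max(1, min(max_leapfrog, round(trajectory_length / eps))))
        n_steps = max(1, int(round(n_steps * rng.uniform(0.8, 1.2))))
        n_steps = min(n_steps, max_leapfrog)

        with np.errstate(over="ignore", invalid="ignore"):
            q_new, p_new, logp_new, grad_new = _leapfrog(logp_grad, q, p0, grad, eps, n_steps, inv_mass)
            h0 = logp - 0.5 * np.sum(inv_mass * p0 * p0)
            if np.isfinite(logp_new):
                h1 = logp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
                delta_h = h1 - h0
            else:
                delta_h = -np.inf
        div = (not np.isfinite(delta_h)) or (delta_h < -_DIVERGENCE_THRESHOLD)
        alpha = 0.0 if div else min(1.0, float(np.exp(min(delta_h, 0.0))))

        if (not div) and rng.uniform() < alpha:
            q, logp, grad = q_new, logp_new, grad_new

        if warming:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            weight = da_count**-kappa
            log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
            eps = float(np.exp(log_eps))

            if w_lo <= it < w_hi:
                window.append(q.copy())
            if it == w_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                inv_mass = np.maximum(var, 1e-6)
                # restart step-size adaptation under the new metric
                eps = _find_initial_step_size(logp_grad, q, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar = 0.0
                h_bar = 0.0
                da_count = 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if da_count > 0 else eps
        else:
            idx = it - n_warmup
            positions[idx] = q
            accept_probs[idx] = alpha
            divergent[idx] = div

    return ChainResult(positions, accept_probs, divergent, eps, inv_mass)
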