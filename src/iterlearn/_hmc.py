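"""Hamiltonian Monte Carlo with dual-averaging step size and diagonal mass
adaptation.

A compact, dependency-free NUTS-less HMC: fixed-length trajectories with
jittered step counts, Stan-style warmup (step-size search, two mass-matrix
re-estimation windows, final step-size freeze).  Sufficient for the smooth,
moderate-dimension posteriors of hierarchical beta regression when the
random effects are non-centered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCResult", "sample_hmc"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray  # (n_chains, n_draws, dim)
    accept_rate: np.ndarray  # (n_chains,)
    step_size: np.ndarray  # (n_chains,)
    divergences: int


def _leapfrog(logp_grad: LogpGrad, q, p, grad, eps, inv_mass, n_steps):
    q, p = q.copy(), p.copy()
    p += 0.5 * eps * grad
    for i in range(n_steps):
        q += eps * inv_mass * p
        logp, grad = logp_grad(q)
        if not np.isfinite(logp):
            return q, p, logp, grad
        p += (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return q, p, logp, grad


def _find_initial_step(logp_grad: LogpGrad, q, inv_mass, rng) -> float:
    """Double/halve the step size until the one-step acceptance crosses 1/2."""
    eps = 0.1
    logp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(inv_mass * p * p)
    _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass, 1)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass, 1)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _DualAveraging:
    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_prob: float) -> float:
        self.t += 1
        t0, gamma, kappa = 10.0, 0.05, 0.75
        w = 1.0 / (self.t + t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / gamma * self.h_bar
        eta = self.t**-kappa
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))


def _regularized_var(samples: np.ndarray) -> np.ndarray:
    n = samples.shape[0]
    var = np.var(samples, axis=0, ddof=1) if n > 1 else np.ones(samples.shape[1])
    return (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))


def sample_hmc(
    logp_grad: LogpGrad,
    init: np.ndarray,
    *,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_leapfrog: int = 24,
) -> HMCResult:
    """Run ``n_chains`` independent HMC chains.

    ``init`` has shape (n_chains, dim); ``logp_grad`` returns the joint log
    density and its gradient.  Draw counts exclude warmup.
    """
    init = np.atleast_2d(np.asarray(init, dtype=float))
    if init.shape[0] != n_chains:
        raise ValueError(f"init has {init.shape[0]} rows for {n_chains} chains")
    dim = init.shape[1]
    chain_rngs = rng.spawn(n_chains)
    draws = np.empty((n_chains, n_draws, dim))
    accept_rates = np.empty(n_chains)
    step_sizes = np.empty(n_chains)
    divergences = 0

    # warmup schedule: [0, s1) step size only; [s1, s2) window 1; [s2, s3)
    # window 2; [s3, end) final step-size polish
    s1 = max(1, int(0.15 * n_warmup))
    s2 = max(s1 + 2, int(0.5 * n_warmup))
    s3 = max(s2 + 2, int(0.9 * n_warmup))

    for c in range(n_chains):
        crng = chain_rngs[c]
        q = init[c].copy()
        inv_mass = np.ones(dim)
        logp, grad = logp_grad(q)
        if not np.isfinite(logp):
            raise ValueError("initial point has non-finite log density")
        eps = _find_initial_step(logp_grad, q, inv_mass, crng)
        da = _DualAveraging(eps, target_accept)
        window: list[np.ndarray] = []
        n_accept = 0.0

        for it in range(n_warmup + n_draws):
            warm = it < n_warmup
            p0 = crng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = logp - 0.5 * np.sum(inv_mass * p0 * p0)
            n_steps = int(crng.integers(1, max_leapfrog + 1))
            q1, p1, logp1, grad1 = _leapfrog(
                logp_grad, q, p0, grad, eps, inv_mass, n_steps
            )
            if np.isfinite(logp1):
                h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
                log_ratio = h1 - h0
                accept_prob = min(1.0, np.exp(min(0.0, log_ratio)))
                if log_ratio < -1000.0:
                    divergences += 0 if warm else 1
            else:
                accept_prob = 0.0
                if not warm:
                    divergences += 1
            if crng.uniform() < accept_prob:
                q, logp, grad = q1, logp1, grad1
            if warm:
                eps = da.update(accept_prob)
                if s1 <= it < s3:
                    window.append(q.copy())
                if it + 1 in (s2, s3):
                    inv_mass = _regularized_var(np.array(window))
                    window = []
                    eps = _find_initial_step(logp_grad, q, inv_mass, crng)
                    da = _DualAveraging(eps, target_accept)
                if it + 1 == n_warmup:
                    eps = float(np.exp(da.log_eps_bar))
            else:
                draws[c, it - n_warmup] = q
                n_accept += accept_prob
        accept_rates[c] = n_accept / n_draws
        step_sizes[c] = eps

    return HMCResult(draws, accept_rates, step_sizes, divergences)
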