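"""Hamiltonian Monte Carlo with warmup adaptation.

A static-trajectory HMC sampler in the style of Stan's adaptive HMC:
leapfrog integration with a diagonal mass matrix, dual-averaging step-size
adaptation toward a target acceptance statistic, and windowed estimation of
the posterior variances (which become the inverse mass) during warmup.
Trajectory lengths are jittered to avoid resonances.

The sampler only needs a callable ``logp_grad(q) -> (log density, gradient)``,
so it is validated independently of the go/no-go likelihood on targets with
known posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChainResult", "sample_chain"]

_DIVERGENCE_DH = 1000.0  # energy error treated as a divergence


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_keep, dim), post-warmup
    logp: np.ndarray           # (n_keep,)
    divergent: np.ndarray      # (n_keep,) bool, sampling phase only
    accept_rate: float
    step_size: float
    inv_mass: np.ndarray


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        m = self.count
        w = 1.0 / (m + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        eta = m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return math.exp(self.log_eps)

    def restart(self, eps0: float) -> None:
        self.mu = math.log(10.0 * eps0)
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0


def _leapfrog(logp_grad, q, p, grad, eps, n_steps, inv_mass):
    """Run ``n_steps`` leapfrog steps; returns (q, p, grad, logp)."""
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, grad, -np.inf
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return q, p, grad, lp


def _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng):
    """Double/halve until a single leapfrog step has acceptance near 0.5."""

    def _energy_after(eps, p):
        _, p1, _, lp1 = _leapfrog(logp_grad, q, p, grad, eps, 1, inv_mass)
        if not np.isfinite(lp1):
            return -np.inf
        with np.errstate(over="ignore"):
            h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        return h1 if np.isfinite(h1) else -np.inf

    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p * p * inv_mass)
    direction = 1.0 if (_energy_after(eps, p) - h0) > math.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        if direction * (_energy_after(eps, p) - h0) < direction * math.log(0.5):
            break
    return max(eps, 1e-10)


def _adaptation_windows(n_warmup: int) -> tuple[int, int, list[int]]:
    """(initial step-size phase, start of terminal phase, variance-window ends)."""
    w_init = max(1, int(0.15 * n_warmup))
    w_term_start = n_warmup - max(1, int(0.10 * n_warmup))
    ends, size, pos = [], max(25, (w_term_start - w_init) // 8), w_init
    while pos + size < w_term_start:
        pos += size
        ends.append(pos)
        size *= 2
    ends.append(w_term_start)
    return w_init, w_term_start, ends


def sample_chain(logp_grad, q0: np.ndarray, n_warmup: int, n_keep: int,
                 rng: np.random.Generator, target_accept: float = 0.8,
                 traj_length: float = 1.2, max_leapfrog: int = 512
                 ) -> ChainResult:
    """Run one adaptive HMC chain.

    Parameters
    ----------
    logp_grad
        Callable ``q -> (log density, gradient)``.
    q0
        Initial position.
    n_warmup, n_keep
        Adaptation iterations (discarded) and retained draws.
    traj_length
        Nominal integration time; the number of leapfrog steps is
        ``traj_length / step_size``, jittered by a U(0.5, 1.5) factor.
    """
    q = np.asarray(q0, dtype=float).copy()
    dim = q.size
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial position has non-finite log density")
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)
    w_init, w_term_start, window_ends = _adaptation_windows(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)
    window_iter = iter(window_ends)
    next_window_end = next(window_iter)

    draws = np.empty((n_keep, dim))
    logps = np.empty(n_keep)
    divergent = np.zeros(n_keep, dtype=bool)
    n_accept = 0

    for it in range(n_warmup + n_keep):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(p0 * p0 * inv_mass)
        n_steps = int(math.ceil(traj_length / eps * rng.uniform(0.5, 1.5)))
        n_steps = min(max(n_steps, 1), max_leapfrog)
        q1, p1, grad1, lp1 = _leapfrog(logp_grad, q, p0, grad, eps, n_steps,
                                       inv_mass)
        if np.isfinite(lp1):
            with np.errstate(over="ignore"):
                h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
            delta = h1 - h0 if np.isfinite(h1) else -np.inf
            diverged = delta < -_DIVERGENCE_DH
            accept_prob = min(1.0, math.exp(min(delta, 0.0)))
        else:
            diverged, accept_prob = True, 0.0
        if not diverged and math.log(rng.random() + 1e-300) < delta:
            q, lp, grad = q1, lp1, grad1
            accepted = True
        else:
            accepted = False

        if warming:
            eps = da.update(accept_prob)
            if w_init <= it < w_term_start:
                welford_n += 1
                d = q - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (q - welford_mean)
                if it + 1 == next_window_end:
                    if welford_n > 4:
                        var = welford_m2 / (welford_n - 1)
                        # Stan-style regularization toward unit scale
                        n_ = welford_n
                        inv_mass = (n_ / (n_ + 5.0)) * var \
                            + 1e-3 * (5.0 / (n_ + 5.0))
                        inv_mass = np.maximum(inv_mass, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    eps = _find_initial_step(logp_grad, q, lp, grad, inv_mass,
                                             rng)
                    da.restart(eps)
                    try:
                        next_window_end = next(window_iter)
                    except StopIteration:
                        next_window_end = -1
            if it + 1 == n_warmup:
                eps = math.exp(da.log_eps_bar)
        else:
            k = it - n_warmup
            draws[k] = q
            logps[k] = lp
            divergent[k] = diverged
            n_accept += accepted

    return ChainResult(draws=draws, logp=logps, divergent=divergent,
                       accept_rate=n_accept / max(n_keep, 1),
                       step_size=eps, inv_mass=inv_mass)
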