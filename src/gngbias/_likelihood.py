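"""Compiled likelihood and gradient kernels for the hierarchical model.

The public model semantics live in :mod:`gngbias.models`; this module
re-implements the same forward pass in numba for speed, adding exact
forward-mode derivatives with respect to the natural-scale parameters
(propagating ``dQ/dtheta`` and ``dV/dtheta`` through the delta-rule
recursion).  Equality with :func:`gngbias.models.subject_loglik` and with
finite differences is enforced by the test suite.

Parameters are handled internally on a fixed 7-slot layout
``(xi, eps, b, pi_rew, pi_pun, rho_rew, rho_pun)``; tied variants (M1/M2)
map their parameters onto several slots via ``slot_src``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .models import POSITIVE, SLOTS, UNIT_INTERVAL, ModelSpec, get_spec

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)

# integer transform codes used inside kernels
_T_PROBIT, _T_EXP, _T_ID = 0, 1, 2
_TCODE = {UNIT_INTERVAL: _T_PROBIT, POSITIVE: _T_EXP}


def transform_codes(spec: ModelSpec) -> np.ndarray:
    return np.array([_TCODE.get(t, _T_ID) for t in spec.transforms], dtype=np.int64)


def slot_source(spec: ModelSpec) -> np.ndarray:
    """For each of the 7 internal slots, the index of the model parameter
    feeding it."""
    src = np.empty(7, dtype=np.int64)
    for j, slot in enumerate(SLOTS):
        for i, name in enumerate(spec.parameter_names):
            if slot in spec.slot_of[name]:
                src[j] = i
                break
        else:  # pragma: no cover - specs always cover all slots
            raise ValueError(f"{spec.variant} does not cover slot {slot}")
    return src


class PackedData:
    """Flat per-trial arrays for a multi-subject trial table."""

    __slots__ = ("subject_ids", "cues", "actions", "feedback", "offsets")

    def __init__(self, table: pd.DataFrame):
        ids = list(dict.fromkeys(table["subjID"]))  # first-appearance order
        self.subject_ids = ids
        cues, acts, fbs, offsets = [], [], [], [0]
        for sid in ids:
            grp = table[table["subjID"] == sid]
            t = grp["trial"].to_numpy()
            if not np.array_equal(t, np.arange(1, len(t) + 1)):
                raise ValueError(f"subject {sid!r}: trials must be ordered 1..n")
            cues.append(grp["cue"].to_numpy(np.int64))
            acts.append(grp["keyPressed"].to_numpy(np.int64))
            fbs.append(grp["outcome"].to_numpy(np.float64))
            offsets.append(offsets[-1] + len(grp))
        self.cues = np.concatenate(cues)
        self.actions = np.concatenate(acts)
        self.feedback = np.concatenate(fbs)
        self.offsets = np.array(offsets, dtype=np.int64)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@njit(cache=True)
def _subj_loglik(nat, cues, acts, fbs, lo, hi):
    """Log-likelihood of one session; ``nat`` is the 7-slot natural vector."""
    xi, eps, b = nat[0], nat[1], nat[2]
    Q = np.zeros((2, 4))
    V = np.zeros(4)
    ll = 0.0
    for t in range(lo, hi):
        s = cues[t] - 1
        rew = s == 0 or s == 2
        pi = nat[3] if rew else nat[4]
        rho = nat[5] if rew else nat[6]
        d = Q[1, s] - Q[0, s] + b + pi * V[s]
        if d >= 0.0:
            sg = 1.0 / (1.0 + math.exp(-d))
        else:
            ed = math.exp(d)
            sg = ed / (1.0 + ed)
        p = sg * (1.0 - xi) + 0.5 * xi
        a = acts[t]
        ll += math.log(p) if a == 1 else math.log(1.0 - p)
        r = fbs[t]
        Q[a, s] += eps * (rho * r - Q[a, s])
        V[s] += eps * (rho * r - V[s])
    return ll


@njit(cache=True)
def _subj_loglik_grad(nat, cues, acts, fbs, lo, hi, grad):
    """Log-likelihood and its gradient w.r.t. the 7 natural slots.

    ``grad`` (length 7) is overwritten.  Derivatives of the latent state are
    propagated forward: dQ/dtheta has an extra trailing axis of size 7.
    """
    xi, eps, b = nat[0], nat[1], nat[2]
    Q = np.zeros((2, 4))
    V = np.zeros(4)
    dQ = np.zeros((2, 4, 7))
    dV = np.zeros((4, 7))
    dd = np.empty(7)
    grad[:] = 0.0
    ll = 0.0
    for t in range(lo, hi):
        s = cues[t] - 1
        rew = s == 0 or s == 2
        ip = 3 if rew else 4
        ir = 5 if rew else 6
        pi = nat[ip]
        rho = nat[ir]
        d = Q[1, s] - Q[0, s] + b + pi * V[s]
        for k in range(7):
            dd[k] = dQ[1, s, k] - dQ[0, s, k] + pi * dV[s, k]
        dd[2] += 1.0
        dd[ip] += V[s]
        if d >= 0.0:
            sg = 1.0 / (1.0 + math.exp(-d))
        else:
            ed = math.exp(d)
            sg = ed / (1.0 + ed)
        p = sg * (1.0 - xi) + 0.5 * xi
        c = sg * (1.0 - sg) * (1.0 - xi)
        a = acts[t]
        # clamp away from 0 so extreme warmup proposals stay differentiable
        if a == 1:
            if p < 1e-300:
                p = 1e-300
            ll += math.log(p)
            inv = 1.0 / p
            for k in range(7):
                grad[k] += c * dd[k] * inv
            grad[0] += (0.5 - sg) * inv
        else:
            q1 = 1.0 - p
            if q1 < 1e-300:
                q1 = 1e-300
            ll += math.log(q1)
            inv = 1.0 / q1
            for k in range(7):
                grad[k] -= c * dd[k] * inv
            grad[0] -= (0.5 - sg) * inv
        r = fbs[t]
        pe_q = rho * r - Q[a, s]
        pe_v = rho * r - V[s]
        for k in range(7):
            dQ[a, s, k] -= eps * dQ[a, s, k]
            dV[s, k] -= eps * dV[s, k]
        dQ[a, s, ir] += eps * r
        dV[s, ir] += eps * r
        dQ[a, s, 1] += pe_q
        dV[s, 1] += pe_v
        Q[a, s] += eps * pe_q
        V[s] += eps * pe_v
    return ll


@njit(cache=True)
def _pointwise_loglik(nat_draws, cues, acts, fbs, offsets):
    """Per-(draw, subject) log-likelihood; nat_draws has shape (D, N, 7)."""
    D, N = nat_draws.shape[0], nat_draws.shape[1]
    out = np.empty((D, N))
    for d in range(D):
        for i in range(N):
            out[d, i] = _subj_loglik(nat_draws[d, i], cues, acts, fbs,
                                     offsets[i], offsets[i + 1])
    return out


@njit(cache=True)
def _mean_pgo(nat_draws, cues, acts, fbs, offsets):
    """One-step-ahead p(go) per trial, averaged over posterior draws.

    For each draw the latent state is rolled forward conditioning on the
    subject's *actual* actions and feedback, so the prediction for trial t
    only uses trials 1..t-1.
    """
    D, N = nat_draws.shape[0], nat_draws.shape[1]
    total = offsets[N]
    acc = np.zeros(total)
    for d in range(D):
        for i in range(N):
            nat = nat_draws[d, i]
            xi, eps, b = nat[0], nat[1], nat[2]
            Q = np.zeros((2, 4))
            V = np.zeros(4)
            for t in range(offsets[i], offsets[i + 1]):
                s = cues[t] - 1
                rew = s == 0 or s == 2
                pi = nat[3] if rew else nat[4]
                rho = nat[5] if rew else nat[6]
                dd = Q[1, s] - Q[0, s] + b + pi * V[s]
                if dd >= 0.0:
                    sg = 1.0 / (1.0 + math.exp(-dd))
                else:
                    ed = math.exp(dd)
                    sg = ed / (1.0 + ed)
                acc[t] += sg * (1.0 - xi) + 0.5 * xi
                a = acts[t]
                r = fbs[t]
                Q[a, s] += eps * (rho * r - Q[a, s])
                V[s] += eps * (rho * r - V[s])
    return acc / D


@njit(cache=True)
def _hier_logpost_grad(q, K, N, slot_src, tcodes, cues, acts, fbs, offsets,
                       prior_mu_sd, prior_sigma_sd, grad_out):
    """Hierarchical log posterior and gradient, non-centered parameterization.

    Sampling vector ``q`` = [mu (K), log_sigma (K), z (N*K)].  Individual
    unconstrained parameter: theta_ik = mu_k + sigma_k * z_ik, constrained per
    transform code.  Priors: mu_k ~ N(0, prior_mu_sd_k), sigma_k ~
    half-Normal(0, prior_sigma_sd_k) (log-scale sampling with Jacobian),
    z ~ N(0, 1).  Additive constants are dropped.
    """
    mu = q[:K]
    phi = q[K:2 * K]
    lp = 0.0
    grad_out[:] = 0.0
    sigma = np.empty(K)
    for k in range(K):
        sigma[k] = math.exp(phi[k])
    nat = np.empty(K)
    dnat = np.empty(K)
    nat7 = np.empty(7)
    g7 = np.empty(7)
    gK = np.empty(K)
    for i in range(N):
        for k in range(K):
            z = q[2 * K + i * K + k]
            theta = mu[k] + sigma[k] * z
            code = tcodes[k]
            if code == 0:  # probit -> (0, 1)
                nat[k] = 0.5 * math.erfc(-theta / _SQRT2)
                dnat[k] = math.exp(-0.5 * theta * theta) * _INV_SQRT2PI
            elif code == 1:  # exp -> (0, inf)
                e = math.exp(theta)
                nat[k] = e
                dnat[k] = e
            else:
                nat[k] = theta
                dnat[k] = 1.0
        for j in range(7):
            nat7[j] = nat[slot_src[j]]
        lp += _subj_loglik_grad(nat7, cues, acts, fbs,
                                offsets[i], offsets[i + 1], g7)
        for k in range(K):
            gK[k] = 0.0
        for j in range(7):
            gK[slot_src[j]] += g7[j]
        for k in range(K):
            z = q[2 * K + i * K + k]
            gt = gK[k] * dnat[k]
            grad_out[k] += gt
            grad_out[K + k] += gt * sigma[k] * z
            grad_out[2 * K + i * K + k] = gt * sigma[k] - z
            lp += -0.5 * z * z
    for k in range(K):
        s2 = prior_mu_sd[k] * prior_mu_sd[k]
        lp += -0.5 * mu[k] * mu[k] / s2
        grad_out[k] += -mu[k] / s2
        ss2 = prior_sigma_sd[k] * prior_sigma_sd[k]
        lp += -0.5 * sigma[k] * sigma[k] / ss2 + phi[k]
        grad_out[K + k] += -sigma[k] * sigma[k] / ss2 + 1.0
    return lp


def group_loglik(nat7: np.ndarray, data: PackedData) -> np.ndarray:
    """Per-subject log-likelihood at one parameter point (N, 7 natural)."""
    n = data.n_subjects
    out = np.empty(n)
    for i in range(n):
        out[i] = _subj_loglik(nat7[i], data.cues, data.actions, data.feedback,
                              data.offsets[i], data.offsets[i + 1])
    return out


def make_logpost(data: PackedData, spec: "ModelSpec | str",
                 prior_mu_sd: np.ndarray, prior_sigma_sd: np.ndarray):
    """Closure ``f(q) -> (logpost, grad)`` over the packed data."""
    spec = get_spec(spec)
    K, N = spec.n_params, data.n_subjects
    src = slot_source(spec)
    tc = transform_codes(spec)
    dim = 2 * K + N * K
    prior_mu_sd = np.asarray(prior_mu_sd, dtype=float)
    prior_sigma_sd = np.asarray(prior_sigma_sd, dtype=float)

    def logpost_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.empty(dim)
        lp = _hier_logpost_grad(q, K, N, src, tc, data.cues, data.actions,
                                data.feedback, data.offsets,
                                prior_mu_sd, prior_sigma_sd, grad)
        return lp, grad

    logpost_grad.dim = dim
    return logpost_grad
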