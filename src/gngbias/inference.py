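"""Hierarchical Bayesian estimation of the go/no-go models.

The posterior is over group-level means ``mu_k`` and SDs ``sigma_k`` (on the
unconstrained scale) and per-subject standard-normal offsets ``z_ik``, with
the individual unconstrained parameter ``theta_ik = mu_k + sigma_k * z_ik``
(non-centered parameterization) pushed through the model's constraining
transforms.  Priors are weakly informative: ``mu_k ~ Normal(0, 1)`` for
unit-interval and positive parameters, ``Normal(0, 10)`` for the
unconstrained go/Pavlovian biases, ``sigma_k ~ half-Normal(0, 1)``,
``z ~ Normal(0, 1)``; all scales are configurable.

Sampling uses the package's adaptive HMC (:mod:`gngbias._hmc`) with analytic
gradients (:mod:`gngbias._likelihood`).  Each group is fitted separately.

The main entry point is the scikit-learn-style estimator :class:`GoNogoHBA`
(``fit`` / ``predict`` / ``get_params``); :func:`fit_hierarchical`,
:func:`diagnostics` and :func:`extract_group_means` are thin functional
wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from . import _hmc
from ._likelihood import (PackedData, _pointwise_loglik, group_loglik,
                          make_logpost, slot_source, transform_codes)
from .models import (POSITIVE, UNCONSTRAINED, UNIT_INTERVAL, ModelSpec,
                     get_spec)
from .task import validate_trials

__all__ = [
    "MCMCConfig",
    "PriorConfig",
    "FitResult",
    "GoNogoHBA",
    "fit_hierarchical",
    "diagnostics",
    "extract_group_means",
    "split_rhat_table",
    "ConvergenceWarning",
]

RHAT_THRESHOLD = 1.1
DIVERGENCE_FRACTION_THRESHOLD = 0.05


class ConvergenceWarning(UserWarning):
    """The sampler ran but its diagnostics do not certify convergence."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; the defaults retain 4 x 2000 = 8000 draws."""

    n_chains: int = 4
    n_warmup: int = 2000
    n_keep_per_chain: int = 2000
    seed: int = 0
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_keep_per_chain) < 1:
            raise ValueError("chain, warmup and keep counts must be >= 1")


@dataclass(frozen=True)
class PriorConfig:
    """Prior scales of the hierarchy (see module docstring for defaults)."""

    mu_sd_bounded: float = 1.0        # unit-interval and positive parameters
    mu_sd_unbounded: float = 10.0     # go bias and Pavlovian biases
    sigma_sd: float = 1.0             # half-normal scale of group SDs

    def mu_sd_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([
            self.mu_sd_unbounded if t == UNCONSTRAINED else self.mu_sd_bounded
            for t in spec.transforms
        ])

    def sigma_sd_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.full(spec.n_params, self.sigma_sd)


def _constrain(theta: np.ndarray, transform: str) -> np.ndarray:
    if transform == UNIT_INTERVAL:
        return ndtr(theta)
    if transform == POSITIVE:
        return np.exp(theta)
    return theta


def split_rhat_table(idata: az.InferenceData, spec: ModelSpec) -> dict:
    """Max split-Rhat per sampled quantity (group means, SDs and offsets)."""
    sampled = [f"{pre}{p}" for p in spec.parameter_names
               for pre in ("mu_", "sigma_", "z_")]
    rhat = az.rhat(idata, var_names=sampled)
    return {v: float(np.max(rhat[v].values)) for v in rhat.data_vars}


@dataclass
class FitResult:
    """Posterior draws plus diagnostics for one group fit."""

    idata: az.InferenceData
    spec: ModelSpec
    subject_ids: list[str]
    pointwise_loglik: np.ndarray      # (total draws, n subjects)
    diagnostics: dict
    converged: bool
    mcmc: MCMCConfig
    data: PackedData = field(repr=False)

    @property
    def n_draws(self) -> int:
        return self.pointwise_loglik.shape[0]

    def group_mean_draws(self, parameter: str) -> np.ndarray:
        """Natural-scale draws of the group mean, flattened over chains."""
        self._check_parameter(parameter)
        return self.idata.posterior[f"group_{parameter}"].values.reshape(-1)

    def subject_param_draws(self, parameter: str) -> np.ndarray:
        """(total draws, n subjects) natural-scale individual draws."""
        self._check_parameter(parameter)
        v = self.idata.posterior[parameter].values
        return v.reshape(-1, v.shape[-1])

    def natural_slot_draws(self) -> np.ndarray:
        """(total draws, n subjects, 7) natural parameters on the slot layout."""
        src = slot_source(self.spec)
        per_param = np.stack(
            [self.subject_param_draws(p) for p in self.spec.parameter_names],
            axis=-1)
        return np.ascontiguousarray(per_param[..., src])

    def _check_parameter(self, parameter: str) -> None:
        if parameter not in self.spec.parameter_names:
            raise KeyError(
                f"unknown parameter {parameter!r}; valid names for "
                f"{self.spec.variant}: {list(self.spec.parameter_names)}")


class GoNogoHBA(BaseEstimator):
    """Hierarchical Bayesian go/no-go model, scikit-learn style.

    Parameters
    ----------
    variant
        Model variant, ``"M1"``, ``"M2"`` or ``"M3"``.
    n_chains, n_warmup, n_keep_per_chain, seed, target_accept
        MCMC settings (defaults: 4 chains x 2000 warmup + 2000 kept).
    mu_sd_bounded, mu_sd_unbounded, sigma_sd
        Prior scales, see :class:`PriorConfig`.
    traj_length
        Nominal HMC integration time.

    Attributes
    ----------
    result_ : FitResult
        Full posterior, diagnostics and pointwise log-likelihood.
    idata_ : arviz.InferenceData
    diagnostics_ : dict
    converged_ : bool

    Examples
    --------
    >>> est = GoNogoHBA(variant="M3", n_chains=2, n_warmup=500,
    ...                 n_keep_per_chain=500, seed=1)
    >>> est.fit(trial_table)                              # doctest: +SKIP
    >>> est.result_.group_mean_draws("pi_pun").mean()     # doctest: +SKIP
    """

    def __init__(self, variant: str = "M3", n_chains: int = 4,
                 n_warmup: int = 2000, n_keep_per_chain: int = 2000,
                 seed: int = 0, target_accept: float = 0.8,
                 mu_sd_bounded: float = 1.0, mu_sd_unbounded: float = 10.0,
                 sigma_sd: float = 1.0, traj_length: float = 1.2):
        self.variant = variant
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_keep_per_chain = n_keep_per_chain
        self.seed = seed
        self.target_accept = target_accept
        self.mu_sd_bounded = mu_sd_bounded
        self.mu_sd_unbounded = mu_sd_unbounded
        self.sigma_sd = sigma_sd
        self.traj_length = traj_length

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, y=None) -> "GoNogoHBA":
        """Sample the hierarchical posterior for one group's trial table."""
        spec = get_spec(self.variant)
        validate_trials(X)
        data = PackedData(X)
        if data.n_subjects < 2:
            raise ValueError("hierarchical fit needs at least 2 subjects")
        priors = PriorConfig(self.mu_sd_bounded, self.mu_sd_unbounded,
                             self.sigma_sd)
        logpost = make_logpost(data, spec, priors.mu_sd_vector(spec),
                               priors.sigma_sd_vector(spec))
        K, N = spec.n_params, data.n_subjects
        dim = logpost.dim

        chains = []
        for cseq in np.random.SeedSequence(self.seed).spawn(self.n_chains):
            rng = np.random.default_rng(cseq)
            q0 = rng.normal(0.0, 0.5, dim)
            q0[K:2 * K] = rng.normal(-1.5, 0.3, K)  # start with small sigmas
            chains.append(_hmc.sample_chain(
                logpost, q0, self.n_warmup, self.n_keep_per_chain, rng,
                target_accept=self.target_accept,
                traj_length=self.traj_length))

        draws = np.stack([c.draws for c in chains])       # (C, D, dim)
        divergent = np.stack([c.divergent for c in chains])
        C, D = draws.shape[:2]
        mu = draws[:, :, :K]
        sigma = np.exp(draws[:, :, K:2 * K])
        z = draws[:, :, 2 * K:].reshape(C, D, N, K)
        theta = mu[:, :, None, :] + sigma[:, :, None, :] * z

        posterior: dict[str, np.ndarray] = {}
        dims: dict[str, list[str]] = {}
        for k, (name, tr) in enumerate(zip(spec.parameter_names,
                                           spec.transforms)):
            posterior[f"mu_{name}"] = mu[..., k]
            posterior[f"sigma_{name}"] = sigma[..., k]
            posterior[f"z_{name}"] = z[..., k]
            posterior[name] = _constrain(theta[..., k], tr)
            posterior[f"group_{name}"] = _constrain(mu[..., k], tr)
            dims[f"z_{name}"] = ["subject"]
            dims[name] = ["subject"]

        self.result_ = self._assemble(posterior, dims, divergent, chains,
                                      data, spec)
        self.idata_ = self.result_.idata
        self.diagnostics_ = self.result_.diagnostics
        self.converged_ = self.result_.converged
        return self

    def _assemble(self, posterior, dims, divergent, chains, data, spec
                  ) -> FitResult:
        nat7_by_draw = None
        # pointwise per-subject log-likelihood for every retained draw
        per_param = np.stack(
            [posterior[p].reshape(-1, data.n_subjects)
             for p in spec.parameter_names], axis=-1)
        nat7_by_draw = np.ascontiguousarray(per_param[..., slot_source(spec)])
        pointwise = _pointwise_loglik(nat7_by_draw, data.cues, data.actions,
                                      data.feedback, data.offsets)
        C, D = divergent.shape
        idata = az.from_dict(
            posterior=posterior,
            dims=dims,
            coords={"subject": data.subject_ids},
            sample_stats={"diverging": divergent},
            log_likelihood={"obs": pointwise.reshape(C, D, data.n_subjects)},
        )
        rhat_table = split_rhat_table(idata, spec)
        n_div = int(divergent.sum())
        diag = {
            "max_rhat": max(rhat_table.values()),
            "rhat": rhat_table,
            "n_divergent": n_div,
            "divergence_fraction": n_div / divergent.size,
            "n_draws": int(C * D),
            "step_sizes": [c.step_size for c in chains],
            "accept_rates": [c.accept_rate for c in chains],
        }
        converged = (diag["max_rhat"] <= RHAT_THRESHOLD
                     and diag["divergence_fraction"]
                     <= DIVERGENCE_FRACTION_THRESHOLD)
        if not converged:
            warnings.warn(
                f"sampler diagnostics flag non-convergence: max Rhat "
                f"{diag['max_rhat']:.3f}, {n_div} divergent transitions",
                ConvergenceWarning, stacklevel=3)
        return FitResult(idata=idata, spec=spec,
                         subject_ids=list(data.subject_ids),
                         pointwise_loglik=pointwise, diagnostics=diag,
                         converged=converged,
                         mcmc=MCMCConfig(self.n_chains, self.n_warmup,
                                         self.n_keep_per_chain, self.seed,
                                         self.target_accept),
                         data=data)

    # -------------------------------------------------------------- predict
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """One-step-ahead posterior-mean p(go) for each trial of ``X``.

        ``X`` must contain the fitted subjects; predictions for trial t
        condition on the subject's actual history through trial t-1.
        """
        from .evaluation import one_step_ahead
        return one_step_ahead(self.result_, X).trial_predictions[
            "p_go"].to_numpy()

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean posterior log-likelihood per subject (higher is better)."""
        from scipy.special import logsumexp
        pw = self.result_.pointwise_loglik
        return float(np.mean(logsumexp(pw, axis=0) - np.log(pw.shape[0])))


def fit_hierarchical(table: pd.DataFrame, spec: "ModelSpec | str" = "M3",
                     mcmc: MCMCConfig | None = None,
                     priors: PriorConfig | None = None) -> FitResult:
    """Fit one group's trial table; functional wrapper over :class:`GoNogoHBA`."""
    mcmc = mcmc or MCMCConfig()
    priors = priors or PriorConfig()
    est = GoNogoHBA(variant=get_spec(spec).variant, n_chains=mcmc.n_chains,
                    n_warmup=mcmc.n_warmup,
                    n_keep_per_chain=mcmc.n_keep_per_chain, seed=mcmc.seed,
                    target_accept=mcmc.target_accept,
                    mu_sd_bounded=priors.mu_sd_bounded,
                    mu_sd_unbounded=priors.mu_sd_unbounded,
                    sigma_sd=priors.sigma_sd)
    return est.fit(table).result_


def diagnostics(fit: FitResult) -> dict:
    """Convergence report: max split-Rhat, per-parameter Rhat table,
    divergence count and retained-draw count."""
    return dict(fit.diagnostics)


def extract_group_means(fit: FitResult, parameter: str) -> np.ndarray:
    """Natural-scale group-mean draws (one per retained draw)."""
    return fit.group_mean_draws(parameter)
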