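"""Rescorla–Wagner go/no-go models with go bias, Pavlovian bias and noise.

Three nested model variants are supported:

* **M1** (5 parameters): irreducible noise ``xi``, learning rate ``eps``, go
  bias ``b``, a single Pavlovian bias ``pi`` and a single outcome sensitivity
  ``rho``.
* **M2** (6): splits outcome sensitivity into ``rho_rew`` / ``rho_pun`` for
  reward- and punishment-domain cues.
* **M3** (7): additionally splits the Pavlovian bias into ``pi_rew`` /
  ``pi_pun``.

Per trial the agent forms action weights

    W(go, s)   = Q(go, s) + b + pi_dom * V(s)
    W(nogo, s) = Q(nogo, s)

and emits *go* with probability
``sigmoid(W_go - W_nogo) * (1 - xi) + xi / 2`` (a "squashed softmax": a
fraction ``xi`` of choices is uniformly random).  After feedback ``r`` in
{-1, 0, +1}, the instrumental value of the chosen action and the Pavlovian
stimulus value are nudged toward the sensitivity-scaled outcome:

    Q(a, s) += eps * (rho_dom * r - Q(a, s))
    V(s)    += eps * (rho_dom * r - V(s))

``V(s)`` updates every trial regardless of the chosen action; it is what the
Pavlovian system couples to the go weight.  Domain-split parameters are
selected by the cue's domain (reward cues only ever yield r in {0, +1} and
punishment cues r in {-1, 0}, so selecting by outcome sign would be
numerically identical in this task).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .task import GO, NOGO, REWARD_DOMAIN

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "SubjectParams",
    "LatentState",
    "action_weights",
    "choice_prob_go",
    "update_state",
    "subject_loglik",
    "transform_params",
    "inverse_transform_params",
]

# transform codes shared with the unconstrained parameterization
UNIT_INTERVAL = "unit_interval"   # probit: standard-normal CDF
POSITIVE = "positive"             # exp
UNCONSTRAINED = "unconstrained"   # identity

#: full parameter slot order used internally for every variant
SLOTS = ("xi", "eps", "b", "pi_rew", "pi_pun", "rho_rew", "rho_pun")


@dataclass(frozen=True)
class ModelSpec:
    """Names, constraints and slot mapping of one model variant."""

    variant: str
    parameter_names: tuple[str, ...]
    transforms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parameter_names) != len(self.transforms):
            raise ValueError("parameter_names and transforms must align")

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def slot_of(self) -> dict[str, tuple[str, ...]]:
        """Map each parameter name to the internal 7-slot names it fills."""
        tied = {
            "pi": ("pi_rew", "pi_pun"),
            "rho": ("rho_rew", "rho_pun"),
        }
        return {p: tied.get(p, (p,)) for p in self.parameter_names}


MODEL_SPECS: dict[str, ModelSpec] = {
    "M1": ModelSpec(
        "M1",
        ("xi", "eps", "b", "pi", "rho"),
        (UNIT_INTERVAL, UNIT_INTERVAL, UNCONSTRAINED, UNCONSTRAINED, POSITIVE),
    ),
    "M2": ModelSpec(
        "M2",
        ("xi", "eps", "b", "pi", "rho_rew", "rho_pun"),
        (UNIT_INTERVAL, UNIT_INTERVAL, UNCONSTRAINED, UNCONSTRAINED,
         POSITIVE, POSITIVE),
    ),
    "M3": ModelSpec(
        "M3",
        ("xi", "eps", "b", "pi_rew", "pi_pun", "rho_rew", "rho_pun"),
        (UNIT_INTERVAL, UNIT_INTERVAL, UNCONSTRAINED, UNCONSTRAINED,
         UNCONSTRAINED, POSITIVE, POSITIVE),
    ),
}


def get_spec(spec: "ModelSpec | str") -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    return MODEL_SPECS[spec]


@dataclass(frozen=True)
class SubjectParams:
    """One agent's parameters, stored on the full 7-slot natural scale.

    Tied variants (M1/M2) simply carry equal values in the split slots;
    construct them with :meth:`from_named` or :func:`transform_params`.
    """

    xi: float
    eps: float
    b: float
    pi_rew: float
    pi_pun: float
    rho_rew: float
    rho_pun: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi <= 1.0 and 0.0 <= self.eps <= 1.0):
            raise ValueError("xi and eps must lie in [0, 1]")
        if self.rho_rew <= 0 or self.rho_pun <= 0:
            raise ValueError("outcome sensitivities must be > 0")

    @classmethod
    def from_named(cls, values: dict[str, float], spec: "ModelSpec | str" = "M3"
                   ) -> "SubjectParams":
        """Build from per-variant named values (e.g. a single ``pi`` for M1)."""
        spec = get_spec(spec)
        slots: dict[str, float] = {}
        for name, v in values.items():
            for slot in spec.slot_of[name]:
                slots[slot] = float(v)
        return cls(**slots)

    def to_named(self, spec: "ModelSpec | str") -> dict[str, float]:
        spec = get_spec(spec)
        return {p: getattr(self, spec.slot_of[p][0]) for p in spec.parameter_names}

    def to_slots(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SLOTS], dtype=float)


@dataclass
class LatentState:
    """Evolving instrumental (Q) and Pavlovian (V) values during a session.

    ``Q`` is indexed ``[action, cue-1]`` with action NOGO=0 / GO=1; ``V`` is
    indexed ``[cue-1]``.  Both start at zero, so the first choice depends only
    on the go bias and noise.
    """

    Q: np.ndarray
    V: np.ndarray

    @classmethod
    def zeros(cls) -> "LatentState":
        return cls(Q=np.zeros((2, 4)), V=np.zeros(4))

    def copy(self) -> "LatentState":
        return LatentState(Q=self.Q.copy(), V=self.V.copy())


def _pi_eff(params: SubjectParams, cue: int) -> float:
    return params.pi_rew if REWARD_DOMAIN[cue] else params.pi_pun


def _rho_eff(params: SubjectParams, cue: int) -> float:
    return params.rho_rew if REWARD_DOMAIN[cue] else params.rho_pun


def action_weights(state: LatentState, params: SubjectParams, cue: int
                   ) -> tuple[float, float]:
    """Action weights ``(W_go, W_nogo)`` for the current cue.

    The go weight carries the go bias and the Pavlovian coupling
    ``pi_dom * V(s)``; the no-go weight is the bare instrumental value.
    """
    s = cue - 1
    w_go = state.Q[GO, s] + params.b + _pi_eff(params, cue) * state.V[s]
    w_nogo = state.Q[NOGO, s]
    return float(w_go), float(w_nogo)


def choice_prob_go(w_go: float, w_nogo: float, xi: float) -> float:
    """Squashed-softmax go probability.

    ``p = sigmoid(W_go - W_nogo) * (1 - xi) + xi / 2`` — the two-option
    softmax written as a logistic of the weight difference, mixed with a
    uniform lapse of mass ``xi``.  Bounded in ``[xi/2, 1 - xi/2]``.
    """
    return float(expit(w_go - w_nogo) * (1.0 - xi) + 0.5 * xi)


def update_state(state: LatentState, cue: int, action: int, feedback: int,
                 params: SubjectParams) -> LatentState:
    """Return the state after one delta-rule update (input state untouched)."""
    new = state.copy()
    s = cue - 1
    rho = _rho_eff(params, cue)
    new.Q[action, s] += params.eps * (rho * feedback - new.Q[action, s])
    new.V[s] += params.eps * (rho * feedback - new.V[s])
    return new


def _session_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = trials["trial"].to_numpy()
    if not np.array_equal(t, np.arange(1, len(t) + 1)):
        raise ValueError("trials must be one subject's ordered session (trial = 1..n)")
    return (trials["cue"].to_numpy(int),
            trials["keyPressed"].to_numpy(int),
            trials["outcome"].to_numpy(int))


def subject_loglik(params: SubjectParams, trials: pd.DataFrame
                   ) -> tuple[float, np.ndarray]:
    """Log-likelihood of one subject's session under the model.

    Deterministic forward pass: per trial compute the action weights from the
    current latent state, the squashed-softmax go probability, accumulate the
    log-probability of the observed action, then update the state with the
    observed action and feedback.

    Returns
    -------
    total, pointwise
        The summed log-likelihood and the per-trial log-probabilities
        (``total == pointwise.sum()``).
    """
    cues, actions, feedback = _session_arrays(trials)
    state = LatentState.zeros()
    pointwise = np.empty(len(cues))
    for i, (s, a, r) in enumerate(zip(cues, actions, feedback)):
        w_go, w_nogo = action_weights(state, params, int(s))
        p_go = choice_prob_go(w_go, w_nogo, params.xi)
        pointwise[i] = np.log(p_go if a == GO else 1.0 - p_go)
        state = update_state(state, int(s), int(a), int(r), params)
    return float(pointwise.sum()), pointwise


def transform_params(unconstrained: np.ndarray, spec: "ModelSpec | str"
                     ) -> SubjectParams:
    """Map an unconstrained real vector to natural-scale parameters.

    Unit-interval parameters go through the standard-normal CDF (probit link),
    positive ones through ``exp``, unconstrained ones pass through.
    """
    spec = get_spec(spec)
    unconstrained = np.asarray(unconstrained, dtype=float)
    if unconstrained.shape != (spec.n_params,):
        raise ValueError(
            f"expected vector of length {spec.n_params} for {spec.variant}, "
            f"got shape {unconstrained.shape}"
        )
    values = {}
    for name, tr, u in zip(spec.parameter_names, spec.transforms, unconstrained):
        if tr == UNIT_INTERVAL:
            values[name] = float(ndtr(u))
        elif tr == POSITIVE:
            values[name] = float(np.exp(u))
        else:
            values[name] = float(u)
    return SubjectParams.from_named(values, spec)


def inverse_transform_params(params: SubjectParams, spec: "ModelSpec | str"
                             ) -> np.ndarray:
    """Inverse of :func:`transform_params` (exact round-trip)."""
    spec = get_spec(spec)
    named = params.to_named(spec)
    out = np.empty(spec.n_params)
    for i, (name, tr) in enumerate(zip(spec.parameter_names, spec.transforms)):
        v = named[name]
        out[i] = ndtri(v) if tr == UNIT_INTERVAL else np.log(v) if tr == POSITIVE else v
    return out
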