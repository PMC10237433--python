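"""Generative simulation: schedules, feedback, agents and two-group studies.

The generator plays the model of :mod:`gngbias.models` forward to produce
trial tables with known ground truth.  The default study template emulates a
two-group (active stimulation vs sham) design — 17 vs 14 subjects, 180 trials
each — with group-level differences in the direction reported for prefrontal
stimulation: lower irreducible noise, go bias and punishment-domain Pavlovian
bias in the active group, with learning rate and outcome sensitivities shared.

All randomness flows from a single seed through a splittable
``numpy.random.SeedSequence`` hierarchy (study → group → subject → trial), so
cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelSpec, SubjectParams, get_spec, transform_params
from .models import LatentState, action_weights, choice_prob_go, update_state
from .task import CUE_CONDITIONS, TaskDesign, validate_trials

__all__ = [
    "GroupHyperParams",
    "StudyConfig",
    "make_schedule",
    "sample_feedback",
    "simulate_subject",
    "sample_group_params",
    "generate_study",
    "default_study_config",
]


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level mean and SD per parameter, on the unconstrained scale.

    Individual parameters are drawn ``Normal(mean_k, sd_k)`` per parameter and
    pushed through the model's constraining transforms — the same hierarchy
    the fitting module estimates.
    """

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same parameters")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("group SDs must be >= 0")

    def for_spec(self, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
        try:
            mu = np.array([self.means[p] for p in spec.parameter_names])
            sd = np.array([self.sds[p] for p in spec.parameter_names])
        except KeyError as e:
            raise ValueError(f"hyperparameters missing {e} for {spec.variant}")
        return mu, sd


@dataclass(frozen=True)
class StudyConfig:
    """Full recipe for one synthetic two-group study."""

    n_subjects_a: int
    n_subjects_b: int
    hyper_a: GroupHyperParams
    hyper_b: GroupHyperParams
    variant: str = "M3"
    design: TaskDesign = field(default_factory=TaskDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_a, self.n_subjects_b) < 1:
            raise ValueError("each group needs at least one subject")


def make_schedule(design: TaskDesign, seed) -> np.ndarray:
    """Seeded uniform shuffle of the balanced cue sequence.

    Returns a length ``4 * n_trials_per_condition`` array of cue ids, each id
    appearing exactly ``n_trials_per_condition`` times.
    """
    rng = np.random.default_rng(seed)
    cues = np.repeat(np.arange(1, 5), design.n_trials_per_condition)
    rng.shuffle(cues)
    return cues


def sample_feedback(cue: int, action: int, design: TaskDesign,
                    rng: np.random.Generator) -> int:
    """Draw one probabilistic feedback.

    The condition's optimal action yields the beneficial outcome (reward +1,
    or a neutral 0 in the punishment domain) with probability
    ``design.contingency``; the other action reverses the probabilities.
    """
    cond = CUE_CONDITIONS[cue]
    beneficial, non_beneficial = cond.feedback_values
    p = design.contingency if action == cond.correct_action else 1.0 - design.contingency
    return beneficial if rng.random() < p else non_beneficial


def simulate_subject(params: SubjectParams, schedule: np.ndarray,
                     rng: np.random.Generator,
                     design: TaskDesign | None = None,
                     subject_id: str = "sim") -> pd.DataFrame:
    """Play one agent through a cue schedule, returning its trial table."""
    design = design or TaskDesign()
    state = LatentState.zeros()
    rows = np.empty((len(schedule), 3), dtype=int)
    for i, cue in enumerate(schedule):
        cue = int(cue)
        w_go, w_nogo = action_weights(state, params, cue)
        p_go = choice_prob_go(w_go, w_nogo, params.xi)
        action = int(rng.random() < p_go)
        feedback = sample_feedback(cue, action, design, rng)
        rows[i] = (cue, action, feedback)
        state = update_state(state, cue, action, feedback, params)
    df = pd.DataFrame({
        "subjID": subject_id,
        "trial": np.arange(1, len(schedule) + 1),
        "cue": rows[:, 0],
        "keyPressed": rows[:, 1],
        "outcome": rows[:, 2],
    })
    return df


def sample_group_params(hyper: GroupHyperParams, n: int, spec: "ModelSpec | str",
                        rng: np.random.Generator) -> list[SubjectParams]:
    """Draw ``n`` agents from the group-level hierarchy."""
    spec = get_spec(spec)
    mu, sd = hyper.for_spec(spec)
    draws = rng.normal(mu, sd, size=(n, spec.n_params))
    return [transform_params(d, spec) for d in draws]


def generate_study(config: StudyConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full two-group study with a ground-truth manifest.

    Returns ``(table_a, table_b, manifest)``.  Schedules are independent
    across subjects.  The manifest records the seed, design, hyperparameters
    and every subject's true parameters (natural scale), enabling recovery
    tests downstream.
    """
    spec = get_spec(config.variant)
    root = np.random.SeedSequence(config.seed)
    seq_a, seq_b = root.spawn(2)
    manifest: dict = {
        "seed": config.seed,
        "variant": spec.variant,
        "design": {
            "n_trials_per_condition": config.design.n_trials_per_condition,
            "contingency": config.design.contingency,
        },
        "groups": {},
    }
    tables = []
    for label, n, hyper, seq in (
        ("A", config.n_subjects_a, config.hyper_a, seq_a),
        ("B", config.n_subjects_b, config.hyper_b, seq_b),
    ):
        param_seq, *subj_seqs = seq.spawn(n + 1)
        params = sample_group_params(hyper, n, spec,
                                     np.random.default_rng(param_seq))
        frames, true_params = [], {}
        for i, (p, s_seq) in enumerate(zip(params, subj_seqs)):
            sid = f"{label}{i + 1:02d}"
            sched_seq, trial_seq = s_seq.spawn(2)
            schedule = make_schedule(config.design, sched_seq)
            frames.append(simulate_subject(
                p, schedule, np.random.default_rng(trial_seq),
                design=config.design, subject_id=sid))
            true_params[sid] = p.to_named(spec)
        table = pd.concat(frames, ignore_index=True)
        validate_trials(table)
        manifest["groups"][label] = {
            "hyper_means": dict(hyper.means),
            "hyper_sds": dict(hyper.sds),
            "subjects": true_params,
        }
        tables.append(table)
    return tables[0], tables[1], manifest


def default_study_config(seed: int = 0, n_a: int = 17, n_b: int = 14
                         ) -> StudyConfig:
    """Study template with realistic group differences.

    Group B ("sham-like") carries noticeable noise, a positive go bias and a
    positive punishment-domain Pavlovian bias; group A ("active-like") has
    lower xi, b and pi_pun.  Learning rate and outcome sensitivities are
    shared.  Means are on the unconstrained scale (probit for xi/eps, log for
    rho): e.g. xi mean −1.3 ≈ 0.10 natural, rho_rew mean 2.5 ≈ 12 natural.
    """
    shared = {"eps": -0.45, "rho_rew": 2.5, "rho_pun": 2.0}
    means_a = {"xi": -1.9, "b": -0.2, "pi_rew": 0.0, "pi_pun": 0.0, **shared}
    means_b = {"xi": -1.3, "b": 1.0, "pi_rew": 0.0, "pi_pun": 0.5, **shared}
    sds = {"xi": 0.3, "eps": 0.3, "b": 0.5, "pi_rew": 0.5, "pi_pun": 0.5,
           "rho_rew": 0.3, "rho_pun": 0.3}
    return StudyConfig(
        n_subjects_a=n_a, n_subjects_b=n_b,
        hyper_a=GroupHyperParams(means_a, dict(sds)),
        hyper_b=GroupHyperParams(means_b, dict(sds)),
        variant="M3", seed=seed,
    )
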