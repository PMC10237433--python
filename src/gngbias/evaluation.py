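"""Model comparison (PSIS-LOO / LOOIC) and one-step-ahead prediction.

LOOIC = −2 · elpd_loo, where elpd_loo is the PSIS-smoothed leave-one-out
expected log pointwise predictive density; lower LOOIC means better expected
out-of-sample fit.  The pointwise unit is the *subject* (each subject's
session log-likelihood summed over trials), matching the exchangeable units
of the hierarchy.

One-step-ahead prediction rolls the latent state forward conditioning on each
subject's actual actions and feedback, so the predicted p(go) for trial t
uses only trials 1..t−1; predictions are averaged over all retained posterior
draws and summarized per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from ._likelihood import PackedData, _mean_pgo
from .inference import FitResult
from .task import CUE_CONDITIONS

__all__ = [
    "LOOResult",
    "PredictionResult",
    "compute_looic",
    "compare_models",
    "one_step_ahead",
    "predict_from_draws",
]


@dataclass(frozen=True)
class LOOResult:
    """PSIS-LOO summary; ``looic == -2 * elpd_loo`` and ``se`` is LOOIC's SE."""

    elpd_loo: float
    looic: float
    se: float
    pareto_k: np.ndarray
    n_units: int


def compute_looic(pointwise: np.ndarray) -> LOOResult:
    """PSIS-LOO from a (draws x units) pointwise log-likelihood matrix.

    Requires at least 100 draws; raises on non-finite entries and on units
    whose log-likelihood is constant across draws (importance weights are
    degenerate there).
    """
    pointwise = np.asarray(pointwise, dtype=float)
    if pointwise.ndim != 2:
        raise ValueError("pointwise must be a (draws, units) matrix")
    n_draws, n_units = pointwise.shape
    if n_draws < 100:
        raise ValueError(f"need >= 100 draws for PSIS-LOO, got {n_draws}")
    if not np.isfinite(pointwise).all():
        raise ValueError("pointwise log-likelihood contains non-finite values")
    spread = pointwise.max(axis=0) - pointwise.min(axis=0)
    if np.any(spread == 0.0):
        bad = np.flatnonzero(spread == 0.0)
        raise ValueError(
            f"degenerate importance weights: units {bad.tolist()} have "
            "identical log-likelihood across all draws")
    idata = az.from_dict(
        # az.loo requires a posterior group for bookkeeping; content unused
        posterior={"_placeholder": np.zeros((1, n_draws))},
        log_likelihood={"obs": pointwise[None, :, :]})
    res = az.loo(idata, pointwise=True)
    elpd = float(res.elpd_loo)
    return LOOResult(elpd_loo=elpd, looic=-2.0 * elpd, se=2.0 * float(res.se),
                     pareto_k=np.asarray(res.pareto_k), n_units=n_units)


def compare_models(loos: dict[str, LOOResult]) -> pd.DataFrame:
    """Rank models by LOOIC (ascending; ties keep input order).

    Returns a frame with columns ``model``, ``elpd_loo``, ``looic``, ``se``,
    ``d_looic`` (difference to the best model) and ``best``.
    """
    if len(loos) < 2:
        raise ValueError("need at least two models to compare")
    units = {r.n_units for r in loos.values()}
    if len(units) != 1:
        raise ValueError(f"models were scored on different unit counts: {units}")
    df = pd.DataFrame({
        "model": list(loos),
        "elpd_loo": [r.elpd_loo for r in loos.values()],
        "looic": [r.looic for r in loos.values()],
        "se": [r.se for r in loos.values()],
    }).sort_values("looic", kind="stable", ignore_index=True)
    df["d_looic"] = df["looic"] - df["looic"].iloc[0]
    df["best"] = df.index == 0
    return df


@dataclass
class PredictionResult:
    """One-step-ahead predictions at trial, condition and cohort level."""

    trial_predictions: pd.DataFrame   # subjID, trial, cue, p_go, keyPressed
    by_condition: pd.DataFrame        # subjID, cue, label, predicted, observed
    subject_correlations: pd.Series
    mean_correlation: float
    unit: str


def _binned_pairs(trials: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    parts = []
    for cue, grp in trials.groupby("cue", sort=True):
        grp = grp.sort_values("trial")
        bins = np.array_split(np.arange(len(grp)), n_bins)
        for bi, idx in enumerate(bins):
            if len(idx) == 0:
                continue
            sub = grp.iloc[idx]
            parts.append({"cue": cue, "bin": bi,
                          "predicted": sub["p_go"].mean(),
                          "observed": (sub["keyPressed"] == 1).mean()})
    return pd.DataFrame(parts)


def one_step_ahead(fit: FitResult, table: pd.DataFrame,
                   unit: str = "condition", n_bins: int = 9
                   ) -> PredictionResult:
    """Posterior-predictive one-step-ahead evaluation.

    Parameters
    ----------
    fit
        A fit produced on ``table`` (the subject sets must match).
    unit
        ``"condition"`` (default): each subject contributes one
        (predicted mean p(go), observed go frequency) pair per condition and
        the per-subject Pearson correlation runs over those 4 pairs.
        ``"trial_bin"``: trials within each condition are split into
        ``n_bins`` consecutive bins, giving ``4 * n_bins`` pairs per subject.
    """
    return predict_from_draws(fit.natural_slot_draws(), fit.subject_ids,
                              table, unit=unit, n_bins=n_bins)


def predict_from_draws(nat7: np.ndarray, subject_ids: list[str],
                       table: pd.DataFrame, unit: str = "condition",
                       n_bins: int = 9) -> PredictionResult:
    """One-step-ahead evaluation from raw per-subject natural-scale draws.

    ``nat7`` has shape (draws, subjects, 7) on the internal slot layout;
    :func:`one_step_ahead` is the high-level entry point.
    """
    if unit not in ("condition", "trial_bin"):
        raise ValueError("unit must be 'condition' or 'trial_bin'")
    data = PackedData(table)
    if data.subject_ids != list(subject_ids):
        raise ValueError(
            "table subjects do not match the fitted subjects: "
            f"{data.subject_ids} vs {list(subject_ids)}")
    p_go = _mean_pgo(nat7, data.cues, data.actions, data.feedback,
                     data.offsets)
    trial_pred = pd.DataFrame({
        "subjID": np.repeat(data.subject_ids,
                            np.diff(data.offsets)),
        "trial": np.concatenate([np.arange(1, hi - lo + 1) for lo, hi in
                                 zip(data.offsets[:-1], data.offsets[1:])]),
        "cue": data.cues,
        "keyPressed": data.actions,
        "p_go": p_go,
    })
    agg = (trial_pred.groupby(["subjID", "cue"], sort=True)
           .agg(predicted=("p_go", "mean"),
                observed=("keyPressed", "mean"))
           .reset_index())
    agg["label"] = agg["cue"].map(lambda c: CUE_CONDITIONS[c].label)
    cors = {}
    for sid in data.subject_ids:
        if unit == "condition":
            sub = agg[agg["subjID"] == sid]
            x, y = sub["predicted"].to_numpy(), sub["observed"].to_numpy()
        else:
            pairs = _binned_pairs(trial_pred[trial_pred["subjID"] == sid],
                                  n_bins)
            x, y = pairs["predicted"].to_numpy(), pairs["observed"].to_numpy()
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            cors[sid] = np.nan  # correlation undefined for flat profiles
        else:
            cors[sid] = float(np.corrcoef(x, y)[0, 1])
    cor_series = pd.Series(cors, name="r")
    return PredictionResult(
        trial_predictions=trial_pred,
        by_condition=agg,
        subject_correlations=cor_series,
        mean_correlation=float(np.nanmean(cor_series.to_numpy())),
        unit=unit,
    )
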