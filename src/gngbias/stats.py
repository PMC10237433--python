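"""Group-level posterior comparisons and behavioral bias statistics.

Posterior group differences follow the "credible if the 95% HDI of the
difference excludes zero" convention.  Because the two groups are fitted
*separately*, their draws carry no natural pairing; the difference is formed
after a seeded random permutation of each fit's pooled draws, which makes the
arbitrary pairing explicit and reproducible (the mean difference is invariant
to it, the HDI endpoints vary only by Monte-Carlo error).

The behavioral indices contrast accuracy in Pavlovian-congruent vs
-incongruent conditions:

    overall    = (go_to_win + nogo_to_avoid) − (nogo_to_win + go_to_avoid)
    reward     =  go_to_win − nogo_to_win
    punishment =  nogo_to_avoid − go_to_avoid
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .inference import FitResult
from .task import CUE_CONDITIONS, validate_trials

__all__ = [
    "hdi",
    "GroupComparison",
    "group_difference",
    "accuracy_by_condition",
    "bias_indices",
    "two_sample_t",
]

_MIN_HDI_DRAWS = 100


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest density interval: the shortest contiguous interval containing
    ``ceil(mass * n)`` of the sorted draws."""
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    n = draws.size
    if n < _MIN_HDI_DRAWS:
        raise ValueError(f"need >= {_MIN_HDI_DRAWS} draws for an HDI, got {n}")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie strictly between 0 and 1")
    k = math.ceil(mass * n)
    widths = draws[k - 1:] - draws[: n - k + 1]
    j = int(np.argmin(widths))
    return float(draws[j]), float(draws[j + k - 1])


@dataclass(frozen=True)
class GroupComparison:
    """Difference of group-mean posteriors (A − B) for one parameter."""

    parameter: str
    difference_draws: np.ndarray
    mean: float
    hdi_low: float
    hdi_high: float
    credible: bool
    mass: float = 0.95


def group_difference(fit_a: FitResult, fit_b: FitResult, parameter: str,
                     seed: int = 0, mass: float = 0.95,
                     require_convergence: bool = True) -> GroupComparison:
    """Posterior difference of a group-mean parameter between two fits.

    ``fit_a`` and ``fit_b`` must share a model variant.  Draws are paired by
    index after a seeded permutation of each fit's pooled draws; the
    difference is taken on the natural scale, and the comparison is credible
    when its HDI excludes zero.
    """
    if fit_a.spec.variant != fit_b.spec.variant:
        raise ValueError("fits use different model variants: "
                         f"{fit_a.spec.variant} vs {fit_b.spec.variant}")
    if require_convergence and not (fit_a.converged and fit_b.converged):
        raise ValueError("one of the fits is flagged non-converged; pass "
                         "require_convergence=False to override")
    a = fit_a.group_mean_draws(parameter)
    b = fit_b.group_mean_draws(parameter)
    rng = np.random.default_rng(seed)
    n = min(a.size, b.size)
    diff = a[rng.permutation(a.size)[:n]] - b[rng.permutation(b.size)[:n]]
    low, high = hdi(diff, mass)
    return GroupComparison(parameter=parameter, difference_draws=diff,
                           mean=float(diff.mean()), hdi_low=low,
                           hdi_high=high, credible=(low > 0.0 or high < 0.0),
                           mass=mass)


def accuracy_by_condition(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion of correct choices per subject and condition.

    Returns a frame indexed by subject with one column per condition label.
    Raises if any subject lacks trials in some condition (the proportion
    would be undefined).
    """
    validate_trials(table)
    correct = {cid: c.correct_action for cid, c in CUE_CONDITIONS.items()}
    labels = {cid: c.label for cid, c in CUE_CONDITIONS.items()}
    tab = table.assign(
        correct=(table["keyPressed"] == table["cue"].map(correct)))
    acc = (tab.groupby(["subjID", "cue"], sort=False)["correct"].mean()
           .unstack("cue"))
    if acc.isna().any().any() or acc.shape[1] < 4:
        missing = [
            (sid, labels[c]) for sid in acc.index
            for c in CUE_CONDITIONS if c not in acc.columns or pd.isna(acc.loc[sid].get(c))
        ]
        raise ValueError(f"empty condition cells (accuracy undefined): {missing}")
    acc = acc.rename(columns=labels)[list(labels.values())]
    return acc.loc[list(dict.fromkeys(table["subjID"]))]  # original order


def bias_indices(acc: pd.DataFrame) -> pd.DataFrame:
    """Pavlovian-bias indices from per-condition accuracies.

    ``overall = reward + punishment`` by construction.
    """
    need = {"go_to_win", "go_to_avoid", "nogo_to_win", "nogo_to_avoid"}
    if not need.issubset(acc.columns):
        raise ValueError(f"accuracy table must contain columns {sorted(need)}")
    reward = acc["go_to_win"] - acc["nogo_to_win"]
    punishment = acc["nogo_to_avoid"] - acc["go_to_avoid"]
    return pd.DataFrame({
        "reward": reward,
        "punishment": punishment,
        "overall": reward + punishment,
    })


def two_sample_t(x, y, paired: bool = False) -> tuple[float, int, float]:
    """Student's t-test, two-sided.

    Unpaired uses the pooled-variance (equal-variance) form with
    ``df = n_x + n_y - 2``; paired requires equal lengths and uses
    ``df = n - 1``.  Returns ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        raise ValueError("both samples have zero variance; t undefined")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal sample sizes")
        res = sps.ttest_rel(x, y)
        df = x.size - 1
    else:
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    return float(res.statistic), int(df), float(res.pvalue)
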