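"""Task structure and trial-level data handling for the orthogonalized go/no-go task.

The task crosses required action (go / no-go) with outcome valence (win a
reward / avoid a punishment), giving four cue conditions.  Trial-level data are
carried through the pipeline as a tidy :class:`pandas.DataFrame` (one row per
trial) with canonical columns ``subjID``, ``trial``, ``cue``, ``keyPressed``,
``outcome`` — a widely used convention for go/no-go trial tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CueCondition",
    "CUE_CONDITIONS",
    "TaskDesign",
    "COLUMNS",
    "TrialValidationError",
    "validate_trials",
    "read_trials",
    "write_trials",
    "apply_exclusions",
    "GO",
    "NOGO",
]

#: action codes
GO = 1
NOGO = 0

#: canonical column names of a trial table
COLUMNS = ("subjID", "trial", "cue", "keyPressed", "outcome")


@dataclass(frozen=True)
class CueCondition:
    """One of the four cue conditions of the orthogonalized go/no-go task."""

    id: int
    domain: str            # "reward" or "punishment"
    correct_action: int    # GO or NOGO
    label: str

    @property
    def feedback_values(self) -> tuple[int, int]:
        """(beneficial, non-beneficial) outcome codes for this cue's domain."""
        return (1, 0) if self.domain == "reward" else (0, -1)


#: fixed bijection cue id -> condition
CUE_CONDITIONS: dict[int, CueCondition] = {
    1: CueCondition(1, "reward", GO, "go_to_win"),
    2: CueCondition(2, "punishment", GO, "go_to_avoid"),
    3: CueCondition(3, "reward", NOGO, "nogo_to_win"),
    4: CueCondition(4, "punishment", NOGO, "nogo_to_avoid"),
}

#: cue id -> True if the cue's outcomes live in the reward domain
REWARD_DOMAIN = {cid: c.domain == "reward" for cid, c in CUE_CONDITIONS.items()}


@dataclass(frozen=True)
class TaskDesign:
    """Design constants of a session.

    Parameters
    ----------
    n_trials_per_condition
        Trials per cue condition (180 total at the default 45).
    contingency
        Probability that the optimal action yields the beneficial outcome.
    """

    n_trials_per_condition: int = 45
    contingency: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.contingency < 1.0):
            raise ValueError("contingency must lie strictly between 0 and 1")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")

    @property
    def n_trials(self) -> int:
        return 4 * self.n_trials_per_condition


class TrialValidationError(ValueError):
    """A trial table violates the task's structural invariants."""


#: default mapping canonical name -> file column name
_DEFAULT_DIALECT = {c: c for c in COLUMNS}


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the task invariants.

    Checks, row by row where applicable: cue ids in 1–4, actions in {0, 1},
    feedback in {−1, 0, 1}, domain/feedback consistency (reward cues never
    yield −1, punishment cues never yield +1), and per-subject trial indices
    that are strictly increasing and gap-free.

    Returns the table unchanged (same object) on success.
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise TrialValidationError(f"missing column(s): {missing}")

    cue = table["cue"].to_numpy()
    act = table["keyPressed"].to_numpy()
    out = table["outcome"].to_numpy()

    def _first_bad(mask: np.ndarray, what: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask)[0])
            raise TrialValidationError(f"row {row}: {what}")

    _first_bad(~np.isin(cue, (1, 2, 3, 4)), "cue outside 1-4")
    _first_bad(~np.isin(act, (0, 1)), "action (keyPressed) outside {0,1}")
    _first_bad(~np.isin(out, (-1, 0, 1)), "feedback (outcome) outside {-1,0,1}")
    reward_cue = np.isin(cue, (1, 3))
    _first_bad(reward_cue & (out == -1), "reward-domain cue with feedback -1")
    _first_bad(~reward_cue & (out == 1), "punishment-domain cue with feedback +1")

    for sid, grp in table.groupby("subjID", sort=False):
        t = grp["trial"].to_numpy()
        if len(t) and (t[0] != 1 or not np.array_equal(t, np.arange(1, len(t) + 1))):
            raise TrialValidationError(
                f"subject {sid!r}: trial indices must be 1..n, strictly "
                "increasing and gap-free"
            )
    return table


def read_trials(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial table from CSV/TSV.

    Parameters
    ----------
    path
        File with a header row; comma- or tab-separated (sniffed).
    dialect
        Optional mapping from canonical column names (``subjID``, ``trial``,
        ``cue``, ``keyPressed``, ``outcome``) to the file's column names.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for canon, col in {**_DEFAULT_DIALECT, **(dialect or {})}.items():
        if col not in df.columns:
            raise TrialValidationError(
                f"column {col!r} (for {canon!r}) not found in {list(df.columns)}"
            )
        rename[col] = canon
    df = df.rename(columns=rename)[list(COLUMNS)]
    df["subjID"] = df["subjID"].astype(str)
    for c in COLUMNS[1:]:
        df[c] = df[c].astype(int)
    return validate_trials(df.reset_index(drop=True))


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a validated trial table to CSV (round-trips with :func:`read_trials`)."""
    validate_trials(table)
    table.loc[:, list(COLUMNS)].to_csv(path, index=False)


def go_to_win_accuracy(table: pd.DataFrame) -> pd.Series:
    """Proportion of go responses on go-to-win cues, per subject."""
    out = {}
    for sid, grp in table.groupby("subjID", sort=False):
        gw = grp[grp["cue"] == 1]
        if len(gw) == 0:
            raise TrialValidationError(
                f"subject {sid!r} has no go-to-win trials; accuracy undefined"
            )
        out[sid] = float((gw["keyPressed"] == GO).mean())
    return pd.Series(out, name="go_to_win_accuracy")


def apply_exclusions(
    table: pd.DataFrame, threshold: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects who failed to learn the easiest (go-to-win) condition.

    A subject is excluded when their proportion of go responses on go-to-win
    cues is strictly below ``threshold`` (default 0.1); such performance in the
    Pavlovian-congruent reward condition indicates task disengagement rather
    than a learning style worth modelling.

    Returns
    -------
    kept, excluded
        The filtered table (untouched rows, original order) and a report frame
        with columns ``subjID`` and ``go_to_win_accuracy`` for the excluded
        subjects.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    validate_trials(table)
    acc = go_to_win_accuracy(table)
    bad = acc[acc < threshold]
    excluded = bad.rename_axis("subjID").reset_index()
    kept = table[~table["subjID"].isin(bad.index)].reset_index(drop=True)
    return kept, excluded
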