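"""Behavioral state labels derived from the outcome sequence.

The late (rule-following) state is the maximal terminal run of consecutive
correct trials; everything before it is the early (trial-and-error) state.
The switch point is the first late trial.  Trials-to-criterion counts all
trials up to the first trial on which the animal has both six consecutive
correct digs and at least two cumulative correct rejections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import CRITERION_REJECTIONS, CRITERION_RUN


@dataclass
class StateLabeling:
    states: np.ndarray  # per trial: "early" | "late"
    switch_point: int  # 1-based index of the first late trial
    n_trials: int

    @property
    def late_mask(self) -> np.ndarray:
        return self.states == "late"

    @property
    def early_mask(self) -> np.ndarray:
        return self.states == "early"


def _outcomes(trials: pd.DataFrame) -> np.ndarray:
    return (trials["outcome"] == "correct").to_numpy()


def label_states(trials: pd.DataFrame) -> StateLabeling:
    """Split the session into early trials and the terminal correct run."""
    correct = _outcomes(trials)
    n = correct.size
    if n == 0 or not correct[-1]:
        raise ValueError("outcome sequence must end with at least one correct trial")
    run = 0
    for c in correct[::-1]:
        if not c:
            break
        run += 1
    switch_point = n - run + 1
    states = np.array(["early"] * (switch_point - 1) + ["late"] * run)
    return StateLabeling(states=states, switch_point=switch_point, n_trials=n)


def trials_to_criterion(
    trials: pd.DataFrame,
    run_length: int = CRITERION_RUN,
    min_rejections: int = CRITERION_REJECTIONS,
) -> int | None:
    """First trial satisfying both criterion conditions, or None if never.

    Correct rejections accumulate across the whole stage; the consecutive
    run counter resets on any error.
    """
    correct = _outcomes(trials)
    rejections = trials["correct_rejection"].to_numpy().astype(bool)
    run = 0
    n_rej = 0
    for i in range(correct.size):
        run = run + 1 if correct[i] else 0
        n_rej += int(rejections[i])
        if run >= run_length and n_rej >= min_rejections:
            return i + 1
    return None


def attach_states(trials: pd.DataFrame, labeling: StateLabeling) -> pd.DataFrame:
    """Return a copy of the trial table with state and switch-point columns."""
    out = trials.copy()
    out["state"] = labeling.states
    out["switch_point"] = labeling.switch_point
    return out
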