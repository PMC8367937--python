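"""Transformed 3-down/1-up staircase and adaptive session simulation.

The difficulty parameter delta_d decreases by one step after three
consecutive correct responses and increases by one step after every error
(Levitt's transformed up/down rule), which makes the procedure converge to
the accuracy level where up- and down-steps balance: 0.5**(1/3) ~ 79.4%
correct for the 3-down rule.  delta_d starts at 0.6, moves in steps of 0.05
and is floored at 0.05.  Sessions where delta_d ever exceeds 1 are flagged
for exclusion (the session is still completed and recorded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.stats import norm

from . import observers
from .task import LONGER, SHORTER, STANDARDS, TrialPlan, make_standard_sequence

__all__ = [
    "START_DELTA_D",
    "STEP",
    "MINIMUM",
    "EXCLUSION_THRESHOLD",
    "StaircaseState",
    "staircase_update",
    "convergence_level",
    "StationaryProbitObserver",
    "run_adaptive_session",
]

START_DELTA_D = 0.6
STEP = 0.05
MINIMUM = 0.05
#: Sessions reaching delta_d above this are flagged for exclusion.
EXCLUSION_THRESHOLD = 1.0


@dataclass(frozen=True)
class StaircaseState:
    delta_d: float = START_DELTA_D
    step: float = STEP
    minimum: float = MINIMUM
    consecutive_correct: int = 0
    history: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.delta_d < self.minimum - 1e-12:
            raise ValueError("delta_d below minimum")
        if self.consecutive_correct not in (0, 1, 2):
            raise ValueError("consecutive_correct must be 0, 1 or 2")


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply the 3-down/1-up rule to one response.

    Errors raise delta_d by one step and reset the counter; the third
    consecutive correct response lowers delta_d by one step (clamped at the
    minimum) and resets the counter.
    """
    history = state.history + ((state.delta_d, bool(correct)),)
    if not correct:
        return replace(state, delta_d=state.delta_d + state.step,
                       consecutive_correct=0, history=history)
    if state.consecutive_correct == 2:
        new_dd = max(state.minimum, state.delta_d - state.step)
        return replace(state, delta_d=new_dd, consecutive_correct=0,
                       history=history)
    return replace(state, consecutive_correct=state.consecutive_correct + 1,
                   history=history)


def convergence_level(n_down: int) -> float:
    """Accuracy at which an n-down/1-up staircase is stationary: 0.5**(1/n)."""
    if n_down < 1:
        raise ValueError("n_down must be >= 1")
    return 0.5 ** (1.0 / n_down)


class StationaryProbitObserver:
    """Memoryless observer with a fixed probit psychometric function.

    Responds correctly with probability Phi(slope * delta_d), independent of
    history — a known-threshold reference observer for validating staircase
    convergence.
    """

    def __init__(self, slope: float):
        if slope <= 0:
            raise ValueError("slope must be positive")
        self.slope = slope

    @classmethod
    def with_threshold(cls, delta_d: float,
                       accuracy: float = convergence_level(3)):
        """Observer whose P(correct) equals ``accuracy`` at the given delta_d."""
        return cls(norm.ppf(accuracy) / delta_d)

    def __call__(self, plan: TrialPlan, rng: np.random.Generator) -> str:
        correct = rng.random() < norm.cdf(self.slope * plan.delta_d)
        truly_longer = plan.comparison > plan.standard
        if correct:
            return LONGER if truly_longer else SHORTER
        return SHORTER if truly_longer else LONGER


def _balanced_directions(standard_seq: np.ndarray,
                         rng: np.random.Generator) -> list[str]:
    """Per-standard 50/50 longer/shorter assignment in random order."""
    directions = [None] * len(standard_seq)
    for s in np.unique(standard_seq):
        idx = np.flatnonzero(standard_seq == s)
        half, odd = divmod(len(idx), 2)
        labels = [LONGER] * half + [SHORTER] * half
        if odd:
            labels.append(LONGER if rng.random() < 0.5 else SHORTER)
        rng.shuffle(labels)
        for i, lab in zip(idx, labels):
            directions[i] = lab
    return directions


def run_adaptive_session(subject: observers.SubjectParams,
                         n_trials: int = 200,
                         seed=None,
                         observer: Callable | None = None,
                         start: float = START_DELTA_D,
                         step: float = STEP,
                         minimum: float = MINIMUM,
                         exclusion_threshold: float = EXCLUSION_THRESHOLD):
    """Run one adaptive session of the roving-standard task.

    The standard sequence is blocked random; comparison directions are
    balanced 50/50 within each standard across the session; delta_d follows
    the 3-down/1-up staircase.  Responses come from the subject's sequential
    observer model unless a stateless ``observer(plan, rng) -> response``
    callable is supplied.

    Returns ``(records, excluded)`` where each record carries the staircase's
    delta_d for that trial in ``staircase_delta_d`` (a plain dict per trial,
    superset of the fixed-design record fields) and ``excluded`` flags
    sessions whose delta_d ever exceeded the exclusion threshold.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    standard_seq = make_standard_sequence(n_trials, rng)
    directions = _balanced_directions(standard_seq, rng)
    stair = StaircaseState(delta_d=start, step=step, minimum=minimum,
                           history=())
    state = None if observer is not None else observers.initial_state(subject)
    records = []
    excluded = False
    for t in range(n_trials):
        plan = TrialPlan(index=t + 1, standard=float(standard_seq[t]),
                         delta_d=stair.delta_d, direction=directions[t])
        if observer is not None:
            response = observer(plan, rng)
            truly_longer = plan.comparison > plan.standard
            correct = (response == LONGER) == truly_longer
            feedback = 0 if correct else (1 if truly_longer else -1)
            row = dict(subject=subject.subject, trial=plan.index,
                       model="external", sigma_m=math.nan,
                       standard_s=plan.standard, comparison_s=plan.comparison,
                       delta_d=plan.delta_d, direction=plan.direction,
                       response=response, correct=correct,
                       feedback_code=feedback, repr_s=math.nan,
                       repr_c=math.nan, gain=math.nan)
        else:
            record, state = observers.simulate_trial(subject, state, plan, rng)
            correct = record.correct
            row = dict(record.__dict__)
        row["staircase_delta_d"] = stair.delta_d
        records.append(row)
        stair = staircase_update(stair, correct)
        if stair.delta_d > exclusion_threshold:
            excluded = True
    return records, excluded
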