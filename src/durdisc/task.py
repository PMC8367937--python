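"""Trial-plan generation for the roving-standard duration-discrimination task.

On every trial a standard duration S (drawn from a small set that roves from
trial to trial) is followed by a comparison C that is a fixed proportion
``delta_d`` shorter or longer than S:

    shorter:  C = S / (1 + delta_d)
    longer:   C = S * (1 + delta_d)

Both directions are symmetric on a log scale: ``|ln C - ln S| = ln(1 + delta_d)``.
All internal computation elsewhere in the package happens on ln(seconds);
durations in these plans are plain seconds.

Two layouts are provided: the blocked random sequence used for adaptive
(staircase) sessions, where each consecutive block of four trials contains
every standard exactly once, and a fully balanced factorial layout
(standard x direction x delta_d, replicated) used for fixed-design model
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "STANDARDS",
    "DEFAULT_DELTA_GRID",
    "SHORTER",
    "LONGER",
    "TrialPlan",
    "make_standard_sequence",
    "comparison_duration",
    "make_fixed_design",
    "geometric_mean",
    "plans_to_frame",
    "write_plans",
]

#: The four roving standard durations, in seconds.
STANDARDS: tuple[float, ...] = (0.3, 0.6, 1.2, 2.4)

#: Default delta_d grid for fixed-design simulations: 21 equally spaced
#: values spanning the adaptive procedure's floor (0.05) and start (0.60).
#: 4 standards x 2 directions x 21 deltas x 5 replications = 840 trials.
DEFAULT_DELTA_GRID: tuple[float, ...] = tuple(np.linspace(0.05, 0.60, 21))

SHORTER = "shorter"
LONGER = "longer"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TrialPlan:
    """One planned trial: standard, proportional difference, and direction.

    ``comparison`` is derived from the other fields at construction time.
    """

    index: int
    standard: float
    delta_d: float
    direction: str
    comparison: float = field(init=False)

    def __post_init__(self):
        if self.standard <= 0:
            raise ValueError(f"standard must be positive, got {self.standard}")
        if self.delta_d <= 0:
            raise ValueError(f"delta_d must be positive, got {self.delta_d}")
        if self.direction not in (SHORTER, LONGER):
            raise ValueError(f"direction must be {SHORTER!r} or {LONGER!r}")
        object.__setattr__(
            self,
            "comparison",
            comparison_duration(self.standard, self.delta_d, self.direction),
        )

    @property
    def delta_d_signed(self) -> float:
        """delta_d signed by direction: positive for longer comparisons."""
        return self.delta_d if self.direction == LONGER else -self.delta_d


def make_standard_sequence(n_trials: int, seed=None,
                           standards: Sequence[float] = STANDARDS) -> np.ndarray:
    """Blocked random sequence of standards: sampling without replacement.

    Consecutive blocks of ``len(standards)`` trials each contain every
    standard exactly once, in random order.  A trailing partial block is the
    prefix of one further random permutation.
    """
    if n_trials <= 0:
        raise ValueError(f"n_trials must be positive, got {n_trials}")
    rng = _as_rng(seed)
    base = np.asarray(standards, dtype=float)
    n_blocks = -(-n_trials // len(base))  # ceil
    seq = np.concatenate([rng.permutation(base) for _ in range(n_blocks)])
    return seq[:n_trials]


def comparison_duration(standard: float, delta_d: float, direction: str) -> float:
    """Comparison duration for a given standard, delta_d and direction."""
    if standard <= 0 or delta_d <= 0:
        raise ValueError("standard and delta_d must be positive")
    if direction == SHORTER:
        return standard / (1.0 + delta_d)
    if direction == LONGER:
        return standard * (1.0 + delta_d)
    raise ValueError(f"unknown direction {direction!r}")


def make_fixed_design(n_trials: int = 840,
                      delta_grid: Iterable[float] = DEFAULT_DELTA_GRID,
                      seed=None,
                      standards: Sequence[float] = STANDARDS) -> list[TrialPlan]:
    """Balanced factorial design in seeded random order.

    Every (standard, direction, delta_d) cell appears equally often, so
    ``n_trials`` must be a multiple of ``len(standards) * 2 * len(delta_grid)``.
    Within each standard, half the comparisons are longer and half shorter.
    """
    grid = tuple(delta_grid)
    n_cells = len(standards) * 2 * len(grid)
    if n_trials <= 0 or n_trials % n_cells:
        raise ValueError(
            f"n_trials={n_trials} is not a positive multiple of the "
            f"{n_cells} design cells")
    reps = n_trials // n_cells
    cells = [(s, dd, direction)
             for s in standards
             for direction in (SHORTER, LONGER)
             for dd in grid] * reps
    rng = _as_rng(seed)
    order = rng.permutation(len(cells))
    return [TrialPlan(index=i + 1, standard=cells[j][0], delta_d=cells[j][1],
                      direction=cells[j][2])
            for i, j in enumerate(order)]


def geometric_mean(durations: Iterable[float]) -> float:
    """exp(mean(ln d)) over positive durations."""
    arr = np.asarray(list(durations), dtype=float)
    if arr.size == 0:
        raise ValueError("empty duration list")
    if np.any(arr <= 0):
        raise ValueError("durations must be positive")
    return float(gmean(arr))


def plans_to_frame(plans: Iterable[TrialPlan], subject=1) -> pd.DataFrame:
    """Tidy frame of trial plans (one row per planned trial)."""
    return pd.DataFrame(
        {
            "subject": subject,
            "trial": [p.index for p in plans],
            "standard_s": [p.standard for p in plans],
            "delta_d": [p.delta_d for p in plans],
            "direction": [p.direction for p in plans],
            "comparison_s": [p.comparison for p in plans],
        }
    )


def write_plans(plans: Iterable[TrialPlan], path, subject=1) -> None:
    plans_to_frame(plans, subject=subject).to_csv(path, index=False,
                                                  float_format="%.12g")
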