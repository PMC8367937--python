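"""Sequential observer models for two-interval duration discrimination.

All three observers share the same sensory front end: a presented duration
``d`` (seconds) is encoded as a noisy log observation

    x = ln(d) + n,    n ~ N(0, sigma_m^2),

so sigma_m is the sensory noise on a log scale and 1/sigma_m^2 the sensory
precision.  They differ in how an internal reference for duration is carried
across observations:

* Kalman-filter observer: maintains a Gaussian prior N(mu_p, var_p) over log
  duration, drifting between observations with process variance ``q``.  Each
  observation is integrated with the gain

      k = (var_p + q) / (var_p + q + var_m),

  after which  mu_p <- (1 - k) mu_p + k x  and  var_p <- k var_m.  Both the
  standard and the comparison update the prior; the trial decision compares
  the posterior means after each.

* IRM1: internal reference I is an exponentially weighted moving average,
  I <- g I + (1 - g) x, updated only by the first interval (the standard);
  the decision compares the raw comparison observation against I.

* IRM2: same reference, but both intervals update it; the decision compares
  the reference after the comparison's update with the reference after the
  standard's update.

The observer responds "longer" whenever its internal representation of the
comparison exceeds its representation of the standard.  Feedback codes on a
trial are 0 for a correct response and, on errors, the sign of the true
difference (+1 when the comparison was actually longer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .task import LONGER, SHORTER, STANDARDS, TrialPlan, geometric_mean

__all__ = [
    "KALMAN",
    "IRM1",
    "IRM2",
    "MODELS",
    "DEFAULT_Q",
    "DEFAULT_G",
    "DEFAULT_SIGMA_M_MEAN",
    "DEFAULT_SIGMA_M_SPREAD",
    "DEFAULT_SIGMA_M_BOUNDS",
    "SensoryParams",
    "KalmanState",
    "IRMState",
    "SubjectParams",
    "TrialRecord",
    "sense",
    "kalman_gain",
    "kalman_update",
    "steady_state_gain",
    "irm_update",
    "decide",
    "initial_state",
    "simulate_trial",
    "sample_subject_population",
    "simulate_experiment",
    "records_to_frame",
    "write_records",
    "read_records",
]

KALMAN = "kalman"
IRM1 = "irm1"
IRM2 = "irm2"
MODELS = (KALMAN, IRM1, IRM2)

#: Process variance of the Kalman observer's drifting prior (log-seconds^2).
DEFAULT_Q = 0.9
#: EWMA weight on the previous internal reference for the IRMs.
DEFAULT_G = 0.15

#: Population distribution of per-subject sensory noise sigma_m,i: a normal
#: with mean parameter 0.2 truncated below.  The spread and lower bound are
#: calibrated so that the simulated Kalman population's average per-update
#: gain is about 0.85 (comparable to the IRMs' 1 - g) while between-subject
#: precision still varies widely; see docs/methods.md.
DEFAULT_SIGMA_M_MEAN = 0.2
DEFAULT_SIGMA_M_SPREAD = 0.25
DEFAULT_SIGMA_M_BOUNDS = (0.25, math.inf)

#: Neutral starting point for priors/references: the log of the geometric
#: mean of the four standards (~0.849 s).
LOG_CENTER = math.log(geometric_mean(STANDARDS))


@dataclass(frozen=True)
class SensoryParams:
    """Sensory noise of the log-duration front end."""

    sigma_m: float

    def __post_init__(self):
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")

    @property
    def var_m(self) -> float:
        return self.sigma_m**2


@dataclass(frozen=True)
class KalmanState:
    """Gaussian prior over log duration plus its noise constants."""

    mu_p: float
    var_p: float
    q: float
    var_m: float

    def __post_init__(self):
        if self.var_p < 0 or self.q < 0 or self.var_m <= 0:
            raise ValueError("variances must be non-negative and var_m > 0")


@dataclass(frozen=True)
class IRMState:
    """Exponentially weighted internal reference (log-seconds)."""

    I: float
    g: float
    variant: str = IRM1

    def __post_init__(self):
        if not 0 <= self.g < 1:
            raise ValueError("g must satisfy 0 <= g < 1")
        if self.variant not in (IRM1, IRM2):
            raise ValueError(f"variant must be {IRM1!r} or {IRM2!r}")


@dataclass(frozen=True)
class SubjectParams:
    """One simulated subject: identity, sensory noise, and model constants."""

    subject: int
    sigma_m: float
    model: str
    q: float = DEFAULT_Q
    g: float = DEFAULT_G

    def __post_init__(self):
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one simulated trial; the unit serialized to CSV."""

    subject: int
    trial: int
    model: str
    sigma_m: float
    standard_s: float
    comparison_s: float
    delta_d: float
    direction: str
    response: str
    correct: bool
    feedback_code: int
    repr_s: float
    repr_c: float
    gain: float  # mean Kalman gain of the trial's two updates; NaN for IRMs


def sense(duration: float, params: SensoryParams, rng: np.random.Generator) -> float:
    """Noisy log observation of a duration (the sensory front end)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return math.log(duration) + rng.normal(0.0, params.sigma_m)


def kalman_gain(var_p_prev: float, q: float, var_m: float) -> float:
    """Weight on the new observation given prior, process and sensory variance."""
    if var_p_prev < 0 or q < 0 or var_m < 0:
        raise ValueError("variances must be non-negative")
    total = var_p_prev + q + var_m
    if total <= 0:
        raise ValueError("at least one variance must be positive")
    return (var_p_prev + q) / total


def kalman_update(state: KalmanState, x: float) -> tuple[KalmanState, float]:
    """One prior update; returns the new state and the gain used."""
    k = kalman_gain(state.var_p, state.q, state.var_m)
    mu = (1.0 - k) * state.mu_p + k * x
    return replace(state, mu_p=mu, var_p=k * state.var_m), k


def steady_state_gain(q: float, var_m: float) -> float:
    """Fixed point of the gain recursion under constant sensory variance.

    The positive root of ``var_m k^2 + q k - q = 0``.
    """
    if q <= 0 or var_m <= 0:
        raise ValueError("q and var_m must be positive")
    return (-q + math.sqrt(q * q + 4.0 * q * var_m)) / (2.0 * var_m)


def irm_update(state: IRMState, x: float) -> IRMState:
    """EWMA reference update: I <- g I + (1 - g) x."""
    return replace(state, I=state.g * state.I + (1.0 - state.g) * x)


def decide(repr_s: float, repr_c: float, rng: np.random.Generator) -> str:
    """'longer' iff the comparison's representation exceeds the standard's.

    Exact ties (a zero-measure event under continuous noise) are broken by a
    fair coin so that degenerate noiseless tests stay unbiased.
    """
    if not (math.isfinite(repr_s) and math.isfinite(repr_c)):
        raise ValueError("representations must be finite")
    if repr_c > repr_s:
        return LONGER
    if repr_c < repr_s:
        return SHORTER
    return LONGER if rng.random() < 0.5 else SHORTER


def initial_state(params: SubjectParams):
    """Fresh observer state: prior/reference centered on the standards' log mean.

    The Kalman prior variance starts at ``var_m + q``, a one-step stationary
    guess; first-trial gains therefore start slightly above steady state.
    """
    var_m = params.sigma_m**2
    if params.model == KALMAN:
        return KalmanState(mu_p=LOG_CENTER, var_p=var_m + params.q,
                           q=params.q, var_m=var_m)
    return IRMState(I=LOG_CENTER, g=params.g, variant=params.model)


def simulate_trial(params: SubjectParams, state, plan: TrialPlan,
                   rng: np.random.Generator):
    """Run one trial through the subject's observer.

    Returns the trial record and the carried-over state.  For IRM1 the
    comparison observation leaves the state untouched.
    """
    sensory = SensoryParams(params.sigma_m)
    x_s = sense(plan.standard, sensory, rng)
    x_c = sense(plan.comparison, sensory, rng)
    gain = math.nan
    if params.model == KALMAN:
        state, k1 = kalman_update(state, x_s)
        repr_s = state.mu_p
        state, k2 = kalman_update(state, x_c)
        repr_c = state.mu_p
        gain = 0.5 * (k1 + k2)
    elif params.model == IRM1:
        state = irm_update(state, x_s)
        repr_s = state.I
        repr_c = x_c
    else:  # IRM2
        state = irm_update(state, x_s)
        repr_s = state.I
        state = irm_update(state, x_c)
        repr_c = state.I
    response = decide(repr_s, repr_c, rng)
    actually_longer = plan.comparison > plan.standard
    correct = (response == LONGER) == actually_longer
    feedback = 0 if correct else (1 if actually_longer else -1)
    record = TrialRecord(
        subject=params.subject, trial=plan.index, model=params.model,
        sigma_m=params.sigma_m, standard_s=plan.standard,
        comparison_s=plan.comparison, delta_d=plan.delta_d,
        direction=plan.direction, response=response, correct=correct,
        feedback_code=feedback, repr_s=repr_s, repr_c=repr_c, gain=gain,
    )
    return record, state


def sample_subject_population(n_subjects: int,
                              model: str = KALMAN,
                              sigma_m_mean: float = DEFAULT_SIGMA_M_MEAN,
                              sigma_m_spread: float = DEFAULT_SIGMA_M_SPREAD,
                              bounds: tuple[float, float] = DEFAULT_SIGMA_M_BOUNDS,
                              seed=None,
                              q: float = DEFAULT_Q,
                              g: float = DEFAULT_G) -> list[SubjectParams]:
    """Draw per-subject sensory noise from a truncated normal distribution."""
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if sigma_m_mean <= 0 or sigma_m_spread <= 0:
        raise ValueError("sigma_m_mean and sigma_m_spread must be positive")
    lo, hi = bounds
    if not (0 <= lo < hi):
        raise ValueError(f"invalid bounds {bounds}")
    rng = np.random.default_rng(seed)
    a = (lo - sigma_m_mean) / sigma_m_spread
    b = (hi - sigma_m_mean) / sigma_m_spread if math.isfinite(hi) else math.inf
    draws = truncnorm.rvs(a, b, loc=sigma_m_mean, scale=sigma_m_spread,
                          size=n_subjects, random_state=rng)
    return [SubjectParams(subject=i + 1, sigma_m=float(s), model=model, q=q, g=g)
            for i, s in enumerate(draws)]


def simulate_experiment(population: Sequence[SubjectParams],
                        design: Sequence[TrialPlan],
                        seed=None,
                        reshuffle_per_subject: bool = True) -> list[TrialRecord]:
    """Simulate every subject sequentially through the design.

    Each subject starts from a fresh observer state and, by default, runs the
    design cells in their own random order (mirroring per-participant
    randomization).  Per-subject random streams are spawned from the master
    seed, so adding subjects does not reshuffle earlier ones.
    """
    if not population:
        raise ValueError("empty population")
    if not design:
        raise ValueError("empty design")
    streams = np.random.SeedSequence(seed).spawn(len(population))
    records: list[TrialRecord] = []
    for params, stream in zip(population, streams):
        rng = np.random.default_rng(stream)
        plans = list(design)
        if reshuffle_per_subject:
            order = rng.permutation(len(plans))
            plans = [replace(plans[j], index=i + 1)
                     for i, j in enumerate(order)]
        state = initial_state(params)
        for plan in plans:
            record, state = simulate_trial(params, state, plan, rng)
            records.append(record)
    return records


_RECORD_COLUMNS = [
    "subject", "trial", "model", "sigma_m", "standard_s", "comparison_s",
    "delta_d", "direction", "response", "correct", "feedback_code",
    "repr_s", "repr_c", "gain",
]


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    return df[_RECORD_COLUMNS]


def write_records(records, path) -> None:
    """Write trial records (or an equivalent frame) to CSV.

    Floats are formatted at 12 significant digits, enough for an exact
    round-trip at that precision.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.12g")


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["correct"] = df["correct"].astype(bool)
    return df
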