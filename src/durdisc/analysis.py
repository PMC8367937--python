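"""Psychometric analysis of duration-discrimination trial tables.

The response model throughout is a binomial probit regression of the
"comparison longer" response on the signed proportional difference
delta_d_signed (+delta_d for longer comparisons, -delta_d for shorter) plus
context regressors:

* ``s_centered``     — ln(standard) centered on the log geometric mean of the
                       standards (so a zero intercept means no overall bias);
* ``prev_accuracy``  — the previous trial's feedback code (-1 error/shorter,
                       0 correct, +1 error/longer);
* ``s_prev1/s_prev2``— centered log standards of trials n-1, n-2;
* ``dd_prev1/2``     — signed delta_d of trials n-1, n-2 (a collinearity-free
                       stand-in for the previous comparison duration).

Per-subject fits summarize each observer by a precision (the delta_d slope)
and a bias expressed as a constant error (the s_centered coefficient divided
by the slope, i.e. the PSE shift per unit of centered log standard).  Model
evidence is compared through BIC-approximated Bayes factors, and subject-level
precision/bias associations through Spearman correlations with Fisher-z
confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task import LONGER, geometric_mean

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PREDICTORS",
    "SUBJECT_FIT_PREDICTORS",
    "PsychFit",
    "CorrelationResult",
    "build_regressors",
    "fit_probit",
    "bayes_factor",
    "pse",
    "bias_precision_by_subject",
    "spearman_ci",
]

#: Context predictors used for pooled signature fits.  ``prev_accuracy`` is
#: deliberately excluded here: the simulated observers ignore feedback, and
#: conditioning on previous correctness (a function of the previous trial's
#: noise and difficulty) induces a spurious previous-comparison effect.
DEFAULT_PREDICTORS = ("delta_d_signed", "s_centered", "s_prev1", "dd_prev1")
#: Full fixed-effect set used for the per-subject GLMs behind the
#: precision-bias correlation (includes the slope-by-standard interaction
#: and the lag-2 standard).
SUBJECT_FIT_PREDICTORS = ("delta_d_signed", "s_centered", "s_x_dd",
                          "prev_accuracy", "s_prev1", "dd_prev1", "s_prev2")


@dataclass(frozen=True)
class PsychFit:
    """A fitted probit response model."""

    coefficients: dict
    bse: dict
    loglik: float
    bic: float
    n_observations: int
    converged: bool

    def zvalue(self, name: str) -> float:
        return self.coefficients[name] / self.bse[name]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self):
        if not (-1 - 1e-12 <= self.ci_low <= self.rho <= self.ci_high <= 1 + 1e-12):
            raise ValueError("confidence bounds must bracket rho within [-1, 1]")


def build_regressors(records: pd.DataFrame) -> pd.DataFrame:
    """Derive response/context regressors from an ordered trial table.

    Records must be sorted by subject then trial; lags are computed within
    subject only, and rows lacking a lag carry NaN there (fits drop them
    listwise for the predictors they use).
    """
    df = records.reset_index(drop=True)
    by_subject = df.groupby("subject", sort=False)
    if not (by_subject["trial"].diff().dropna() > 0).all():
        raise ValueError("records must be ordered by subject then trial")
    gm = geometric_mean(np.unique(df["standard_s"]))
    out = pd.DataFrame({
        "subject": df["subject"],
        "trial": df["trial"],
        "response_longer": (df["response"] == LONGER).astype(int),
        "delta_d_signed": np.where(df["direction"] == LONGER,
                                   df["delta_d"], -df["delta_d"]),
        "s_centered": np.log(df["standard_s"]) - math.log(gm),
    })
    grouped = out.groupby("subject", sort=False)
    out["s_prev1"] = grouped["s_centered"].shift(1)
    out["s_prev2"] = grouped["s_centered"].shift(2)
    out["dd_prev1"] = grouped["delta_d_signed"].shift(1)
    out["dd_prev2"] = grouped["delta_d_signed"].shift(2)
    out["prev_accuracy"] = df.groupby("subject", sort=False)["feedback_code"].shift(1)
    out["s_x_dd"] = out["s_centered"] * out["delta_d_signed"]
    return out


def _fit_one(rows: pd.DataFrame, predictors) -> PsychFit:
    cols = list(predictors)
    data = rows[["response_longer", *cols]].dropna()
    if len(data) < len(cols) + 2:
        raise ValueError("too few trials to fit")
    y = data["response_longer"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("all responses identical: perfect separation")
    X = sm.add_constant(data[cols], has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        res = model.fit(maxiter=200)
        converged = bool(res.converged) and np.all(np.isfinite(res.params))
    except Exception:  # separation or numerical failure
        logger.warning("probit fit failed; flagged non-converged")
        return PsychFit({}, {}, math.nan, math.nan, len(data), False)
    return PsychFit(
        coefficients=dict(res.params),
        bse=dict(res.bse),
        loglik=float(res.llf),
        bic=float(-2.0 * res.llf + len(res.params) * math.log(len(data))),
        n_observations=len(data),
        converged=converged,
    )


def fit_probit(rows: pd.DataFrame, predictors=DEFAULT_PREDICTORS,
               hierarchy: str = "pooled"):
    """Maximum-likelihood probit regression of ``response_longer``.

    ``hierarchy='pooled'`` fits all rows at once and returns one
    :class:`PsychFit`; ``'per_subject'`` returns ``{subject: PsychFit}`` with
    non-converged subjects flagged (and counted in the log).
    """
    if hierarchy == "pooled":
        return _fit_one(rows, predictors)
    if hierarchy != "per_subject":
        raise ValueError("hierarchy must be 'pooled' or 'per_subject'")
    fits = {}
    n_bad = 0
    for subject, sub in rows.groupby("subject", sort=False):
        try:
            fit = _fit_one(sub, predictors)
        except ValueError:  # too few trials or unanimous responses
            fit = PsychFit({}, {}, math.nan, math.nan, len(sub), False)
        if not fit.converged:
            n_bad += 1
        fits[subject] = fit
    if n_bad:
        logger.warning("%d of %d per-subject fits did not converge",
                       n_bad, len(fits))
    return fits


def bayes_factor(bic_model0: float, bic_model1: float) -> float:
    """BF01 = exp((BIC1 - BIC0) / 2); values below 1 favor model 1."""
    if not (math.isfinite(bic_model0) and math.isfinite(bic_model1)):
        raise ValueError("BIC values must be finite")
    return math.exp((bic_model1 - bic_model0) / 2.0)


def pse(fit: PsychFit, standard: float,
        standards=None) -> float:
    """Point of subjective equality: the comparison duration at which the
    fitted probability of 'longer' is one half, for a given standard.

    Solves the linear predictor for the signed delta_d at which it crosses
    zero (lag terms held at zero) and maps that back to seconds through the
    comparison-duration formulas.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    coef = fit.coefficients
    # center the standard the same way the regressors do
    from .task import STANDARDS
    gm = geometric_mean(standards if standards is not None else STANDARDS)
    s_c = math.log(standard) - math.log(gm)
    slope = coef.get("delta_d_signed", 0.0) + coef.get("s_x_dd", 0.0) * s_c
    if slope == 0:
        raise ValueError("zero psychometric slope; PSE undefined")
    delta_star = -(coef.get("const", 0.0) + coef.get("s_centered", 0.0) * s_c) / slope
    if delta_star >= 0:
        return standard * (1.0 + delta_star)
    return standard / (1.0 - delta_star)


def bias_precision_by_subject(records: pd.DataFrame,
                              predictors=SUBJECT_FIT_PREDICTORS) -> pd.DataFrame:
    """Per-subject precision and bias from individual probit GLMs.

    precision: the delta_d_signed coefficient (psychometric slope).
    bias_coef: the s_centered coefficient (effect of the current standard).
    bias: the constant error, bias_coef / precision — the PSE shift per unit
    of centered log standard, which puts subjects of different precision on a
    common scale.

    Non-converged subjects are dropped (count logged).
    """
    rows = build_regressors(records) if "response_longer" not in records else records
    fits = fit_probit(rows, predictors, hierarchy="per_subject")
    out = []
    for subject, fit in fits.items():
        if not fit.converged:
            continue
        precision = fit.coefficients["delta_d_signed"]
        bias_coef = fit.coefficients["s_centered"]
        out.append(dict(subject=subject, precision=precision,
                        bias_coef=bias_coef,
                        bias=bias_coef / precision if precision else math.nan))
    dropped = len(fits) - len(out)
    if dropped:
        logger.warning("dropped %d non-converged subjects", dropped)
    return pd.DataFrame(out, columns=["subject", "precision", "bias_coef",
                                      "bias"])


def spearman_ci(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation with a Fisher z-transform interval.

    Ties get average ranks; the interval is tanh(atanh(rho) +/- z/sqrt(n-3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    half = stats.norm.ppf(0.5 + confidence / 2.0) / math.sqrt(n - 3)
    return CorrelationResult(rho=rho, ci_low=math.tanh(z - half),
                             ci_high=math.tanh(z + half), n=n)
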