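"""End-to-end orchestration: simulate observer populations, analyze, compare.

`run_model_comparison` is the package's headline computation.  For each
requested observer model it simulates a population on the balanced fixed
design, builds the context regressors, fits pooled and per-subject probit
models, and summarizes (i) the subject-level precision-bias correlation,
(ii) the pooled context-coefficient table (current standard, previous
standard, previous comparison), (iii) PSEs per standard, and for the Kalman
model (iv) the average per-update gain.  `run_staircase_demo` simulates
adaptive 3-down/1-up sessions instead and reports accuracy, exclusions and
staircase stabilization diagnostics.

One master seed drives everything; per-subject streams are spawned from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, observers, staircase, task

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_model_comparison", "run_staircase_demo",
           "simulate_records", "summarize_records"]


@dataclass
class RunConfig:
    """Flat, serializable configuration for a pipeline run."""

    models: tuple = observers.MODELS
    n_subjects: int = 200
    n_trials: int = 840
    design: str = "fixed"  # "fixed" | "staircase"
    sigma_m_mean: float = observers.DEFAULT_SIGMA_M_MEAN
    sigma_m_spread: float = observers.DEFAULT_SIGMA_M_SPREAD
    sigma_m_bounds: tuple = observers.DEFAULT_SIGMA_M_BOUNDS
    q: float = observers.DEFAULT_Q
    g: float = observers.DEFAULT_G
    delta_grid: tuple = task.DEFAULT_DELTA_GRID
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        d["sigma_m_bounds"] = [self.sigma_m_bounds[0],
                               None if math.isinf(self.sigma_m_bounds[1])
                               else self.sigma_m_bounds[1]]
        d["delta_grid"] = [float(x) for x in self.delta_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "models" in d:
            d["models"] = tuple(d["models"])
        if "sigma_m_bounds" in d:
            lo, hi = d["sigma_m_bounds"]
            d["sigma_m_bounds"] = (lo, math.inf if hi is None else hi)
        if "delta_grid" in d:
            d["delta_grid"] = tuple(d["delta_grid"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage(name: str, t0: float, **extra):
    logger.info("stage=%s elapsed=%.1fs %s", name, time.time() - t0,
                " ".join(f"{k}={v}" for k, v in extra.items()))


def simulate_records(model: str, config: RunConfig,
                     seed_offset: int = 0) -> pd.DataFrame:
    """Simulate one model population on the fixed design; returns the table."""
    seed = config.seed + seed_offset
    population = observers.sample_subject_population(
        config.n_subjects, model=model,
        sigma_m_mean=config.sigma_m_mean,
        sigma_m_spread=config.sigma_m_spread,
        bounds=config.sigma_m_bounds,
        seed=seed, q=config.q, g=config.g)
    design = task.make_fixed_design(config.n_trials, config.delta_grid,
                                    seed=seed + 1)
    records = observers.simulate_experiment(population, design, seed=seed + 2)
    return observers.records_to_frame(records)


def summarize_records(model: str, records: pd.DataFrame):
    """Full psychometric summary of one model's record table.

    Returns ``(summary, bias_precision)``: the summary dict used in
    comparison reports and the per-subject precision/bias frame.
    """
    rows = analysis.build_regressors(records)
    try:
        pooled = analysis.fit_probit(rows, analysis.DEFAULT_PREDICTORS, "pooled")
    except ValueError:  # degenerate smoke-scale input
        pooled = analysis.PsychFit({}, {}, math.nan, math.nan, len(rows), False)
        logger.warning("model=%s: pooled fit degenerate", model)
    bp = analysis.bias_precision_by_subject(records)
    try:
        corr = analysis.spearman_ci(bp["precision"], bp["bias"])
    except ValueError:  # too few converged subjects for a correlation
        corr = None
        logger.warning("model=%s: precision-bias correlation unavailable", model)
    pses = {}
    if pooled.converged:
        try:
            fit_for_pse = analysis.fit_probit(
                rows, ("delta_d_signed", "s_centered", "s_x_dd"), "pooled")
            for s in sorted(records["standard_s"].unique()):
                pses[f"{s:g}"] = analysis.pse(fit_for_pse, float(s))
        except ValueError:
            logger.warning("model=%s: PSE fit degenerate", model)
    summary = {
        "model": model,
        "n_subjects": int(records["subject"].nunique()),
        "n_trials": int(len(records)),
        "accuracy": float(records["correct"].mean()),
        "rho": corr.rho if corr else math.nan,
        "rho_ci": [corr.ci_low, corr.ci_high] if corr else [math.nan, math.nan],
        "rho_n": corr.n if corr else len(bp),
        "coefficients": {k: float(v) for k, v in pooled.coefficients.items()},
        "coefficient_z": {k: float(pooled.zvalue(k))
                          for k in pooled.coefficients},
        "bic": pooled.bic,
        "pse_s": pses,
    }
    if model == observers.KALMAN:
        summary["mean_gain"] = float(records["gain"].mean())
    return summary, bp


def run_model_comparison(config: RunConfig) -> dict:
    """Simulate and analyze every model in the config; optionally write files.

    Returns a report dict with one summary per model.  If ``config.outdir``
    is set, writes ``records_<model>.csv``, ``bias_precision_<model>.csv``,
    ``comparison.json`` and the config used.
    """
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.save(outdir / "config.yaml")
    report = {"seed": config.seed, "models": {}}
    for model in config.models:
        records = simulate_records(model, config)
        _stage("simulate", t0, model=model, n=len(records),
               seed=config.seed)
        summary, bp = summarize_records(model, records)
        _stage("analyze", t0, model=model,
               rho=f"{summary['rho']:.3f}")
        report["models"][model] = summary
        if outdir:
            observers.write_records(records, outdir / f"records_{model}.csv")
            bp.to_csv(outdir / f"bias_precision_{model}.csv", index=False,
                      float_format="%.12g")
    if outdir:
        (outdir / "comparison.json").write_text(
            json.dumps(report, indent=2))
    _stage("done", t0)
    return report


def run_staircase_demo(config: RunConfig) -> dict:
    """Simulate adaptive sessions for one population and summarize them.

    Reports overall accuracy, the exclusion count (delta_d exceeding 1), and
    the windowed standard deviation of delta_d as a stabilization diagnostic.
    """
    if config.design != "staircase":
        raise ValueError("run_staircase_demo requires design='staircase'")
    t0 = time.time()
    model = config.models[0] if config.models else observers.KALMAN
    population = observers.sample_subject_population(
        config.n_subjects, model=model,
        sigma_m_mean=config.sigma_m_mean,
        sigma_m_spread=config.sigma_m_spread,
        bounds=config.sigma_m_bounds,
        seed=config.seed, q=config.q, g=config.g)
    streams = np.random.SeedSequence(config.seed + 7).spawn(len(population))
    all_rows, n_excluded = [], 0
    for params, stream in zip(population, streams):
        rows, excluded = staircase.run_adaptive_session(
            params, n_trials=config.n_trials, seed=stream)
        n_excluded += excluded
        all_rows.extend(rows)
    df = pd.DataFrame(all_rows)
    _stage("staircase", t0, model=model, subjects=len(population))
    window = 20
    df["window"] = (df["trial"] - 1) // window
    wsd = (df.groupby(["subject", "window"])["staircase_delta_d"].std()
             .groupby("window").mean())
    report = {
        "model": model,
        "n_subjects": len(population),
        "n_trials": int(config.n_trials),
        "accuracy": float(df["correct"].mean()),
        "n_excluded": int(n_excluded),
        "delta_d_sd_by_window": {str(int(w) * window + 1): float(v)
                                 for w, v in wsd.items()},
        "final_delta_d_mean": float(
            df[df["trial"] > config.n_trials // 2]
            .groupby("subject")["staircase_delta_d"].mean().mean()),
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "staircase_records.csv", index=False,
                  float_format="%.12g")
        (outdir / "staircase.json").write_text(json.dumps(report, indent=2))
    return report
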