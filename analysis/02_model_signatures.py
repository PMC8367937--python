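"""Psychometric signatures that discriminate the observer models.

Reads the trial tables written by 01_simulate_models.py and, per model,
reports the three discriminating signatures:

  1. global context — the pooled probit coefficient for the centered log
     standard is positive in every model;
  2. n-1 assimilation — the previous standard's coefficient is negative in
     every model, but the previous comparison's coefficient is negative only
     for observers that update their reference with both intervals (Kalman,
     IRM2), not IRM1;
  3. precision vs. bias — the subject-level Spearman correlation between
     psychometric slope and constant error is strongly negative only for the
     Kalman observer, whose update weight depends on sensory precision.

Writes results/comparison.json and per-model bias/precision tables.
"""

import json
from pathlib import Path

from durdisc import observers, pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    report = {"models": {}}
    for model in observers.MODELS:
        path = RESULTS / f"records_{model}.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing; run 01_simulate_models.py first")
        records = observers.read_records(path)
        summary, bp = pipeline.summarize_records(model, records)
        report["models"][model] = summary
        bp.to_csv(RESULTS / f"bias_precision_{model}.csv", index=False,
                  float_format="%.12g")
        z = summary["coefficient_z"]
        print(f"\n{model} (n={summary['n_subjects']} subjects)")
        print(f"  accuracy                {summary['accuracy']:.3f}")
        print(f"  s_centered   coef z     {z['s_centered']:+8.1f}")
        print(f"  s_prev1      coef z     {z['s_prev1']:+8.1f}")
        print(f"  dd_prev1     coef z     {z['dd_prev1']:+8.1f}")
        print(f"  precision-bias rho      {summary['rho']:+.3f} "
              f"[{summary['rho_ci'][0]:+.3f}, {summary['rho_ci'][1]:+.3f}]")
        if "mean_gain" in summary:
            print(f"  mean Kalman gain        {summary['mean_gain']:.3f}")
    (RESULTS / "comparison.json").write_text(json.dumps(report, indent=2))
    print(f"\nwrote {RESULTS / 'comparison.json'}")


if __name__ == "__main__":
    main()
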