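"""Adaptive 3-down/1-up sessions for a simulated cohort.

Runs 46 Kalman-observer subjects through 200-trial adaptive sessions (the
human-session layout: blocked roving standards, delta_d staircase starting
at 0.6, step 0.05, floor 0.05) and reports overall accuracy against the
staircase's theoretical convergence level (79.4% for 3-down/1-up), the
number of sessions flagged for exclusion (delta_d exceeding 1), and how the
trial-windowed spread of delta_d stabilizes over the session.
"""

import json
import sys
from pathlib import Path

from durdisc import pipeline
from durdisc.staircase import convergence_level

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    OUT.mkdir(exist_ok=True)
    config = pipeline.RunConfig(models=("kalman",), n_subjects=46,
                                n_trials=200, design="staircase", seed=SEED,
                                outdir=str(OUT))
    report = pipeline.run_staircase_demo(config)
    print(f"subjects          {report['n_subjects']}")
    print(f"overall accuracy  {report['accuracy']:.3f} "
          f"(3-down/1-up convergence level {convergence_level(3):.3f})")
    print(f"excluded          {report['n_excluded']}")
    print(f"mean delta_d, 2nd session half  {report['final_delta_d_mean']:.3f}")
    print("sd of delta_d by 20-trial window:")
    for start, sd in report["delta_d_sd_by_window"].items():
        print(f"  trials {int(start):3d}+  {sd:.3f}")
    (OUT / "staircase.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
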