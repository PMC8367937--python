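"""Simulate the three observer populations on the fixed factorial design.

Generates 200 subjects x 840 trials for each of the Kalman-filter, IRM1 and
IRM2 observers (per-subject sensory noise drawn from the calibrated
truncated normal; q = 0.9, g = 0.15) and writes one trial table per model to
results/records_<model>.csv.  These tables are the input for
02_model_signatures.py.
"""

import sys
from pathlib import Path

from durdisc import observers, pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    OUT.mkdir(exist_ok=True)
    config = pipeline.RunConfig(seed=SEED)
    config.save(OUT / "config.yaml")
    for model in observers.MODELS:
        records = pipeline.simulate_records(model, config)
        path = OUT / f"records_{model}.csv"
        observers.write_records(records, path)
        print(f"{model}: {records['subject'].nunique()} subjects, "
              f"{len(records)} trials, overall accuracy "
              f"{records['correct'].mean():.3f} -> {path.name}")


if __name__ == "__main__":
    main()
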