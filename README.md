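# durdisc

Sequential observer models for **roving-standard duration discrimination**,
with the psychometric machinery to tell them apart.

In a two-interval duration discrimination trial an observer hears/sees a
standard duration *S* (here 0.3, 0.6, 1.2 or 2.4 s, changing from trial to
trial) followed by a comparison *C* = *S*/(1+Δd) or *S*·(1+Δd), and reports
which was longer. Human judgements in this task are pulled toward the
overall duration distribution (global context) and toward the durations of
the immediately preceding trial (local, n−1 context). `durdisc` implements
and simulates three process models of these context effects, all sharing a
noisy log-duration front end `x = ln d + ε`, `ε ~ N(0, σ_m²)`:

* **Kalman-filter observer** — a Bayesian dynamic prior `N(μ_p, σ_p²)` over
  log duration, updated by *every* observation with gain

  ```
  k = (σ_p² + q) / (σ_p² + q + σ_m²),    μ_p ← (1−k) μ_p + k x,    σ_p² ← k σ_m²
  ```

  where `q` is the process variance of the drifting prior. The trial
  decision compares the posterior means after the standard and after the
  comparison. Because `k` depends on σ_m, *more precise observers are less
  biased by context* — the model's signature prediction.
* **IRM1** — an internal reference `I ← g·I + (1−g)·x` (an exponentially
  weighted moving average with fixed weight `g`) updated **only by the first
  interval**; the decision compares the raw comparison observation with `I`.
* **IRM2** — the same reference updated by **both** intervals.

The package simulates populations of such observers on the balanced
factorial design (or through an adaptive 3-down/1-up staircase), then fits
probit psychometric regressions with sequential-history regressors and asks
which qualitative signatures each model reproduces: the global-context
effect of the current standard, assimilation toward the previous standard
and previous comparison, and the subject-level correlation between
psychometric slope (precision) and constant error (bias).

## Worked example

Simulate the three model populations (200 subjects × 840 trials each) and
run the full analysis:

```
python analysis/01_simulate_models.py      # writes results/records_<model>.csv
python analysis/02_model_signatures.py     # fits + comparison table
python analysis/03_staircase_sessions.py   # adaptive-session demo
```

`02_model_signatures.py` prints, for the default seed:

```
kalman (n=200 subjects)
  accuracy                0.685
  s_centered   coef z        +60.2
  s_prev1      coef z        -57.9
  dd_prev1     coef z        -19.2
  precision-bias rho      -0.849 [-0.884, -0.805]
  mean Kalman gain        0.849

irm1 (n=200 subjects)
  accuracy                0.683
  s_centered   coef z        +65.1
  s_prev1      coef z        -54.9
  dd_prev1     coef z         +1.0
  precision-bias rho      +0.010 [-0.129, +0.149]

irm2 (n=200 subjects)
  accuracy                0.683
  s_centered   coef z        +64.5
  s_prev1      coef z        -63.4
  dd_prev1     coef z        -20.7
  precision-bias rho      +0.027 [-0.112, +0.165]
```

Reading the table: all three models show a positive effect of the current
(log-centered) standard (`s_centered`) — global context — and a negative
effect of the previous standard (`s_prev1`) — n−1 assimilation. Only the
models that fold the *comparison* into their reference (Kalman, IRM2)
produce a negative effect of the previous comparison (`dd_prev1`, the
signed Δd of trial n−1); for IRM1 that coefficient is statistically
indistinguishable from zero. Finally, only the Kalman observer — whose
update weight is precision-dependent — produces a strong negative Spearman
correlation between each subject's psychometric slope and constant error;
for both IRMs, which share a fixed weight `g`, the correlation straddles
zero. The mean Kalman gain (≈0.85 per update at `q = 0.9`) matches the
IRMs' new-observation weight `1 − g = 0.85`, making the models directly
comparable.

The same pipeline is scriptable:

```
durdisc simulate --model kalman --subjects 200 --trials 840 --seed 1 --out run/
durdisc analyze --in run/records.csv --out run/
durdisc compare --config my_config.yaml --out cmp/
```

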