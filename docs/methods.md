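# Methods

## Task and stimulus model

All computation is carried out on log durations (natural log of seconds).
The two comparison directions, C = S/(1+Δd) and C = S·(1+Δd), are exactly
symmetric on that scale (|ln C − ln S| = ln(1+Δd)), so the signed quantity
`delta_d_signed = ±Δd` is the natural difficulty axis and any fixed time
unit cancels out of every model decision. The four standards 0.3, 0.6, 1.2
and 2.4 s are log-spaced around their geometric mean (0.849 s ≈ 849 ms),
which is therefore the natural centering point: `s_centered = ln S − ln 0.849`
makes a zero probit intercept mean "no overall bias".

Two trial layouts are generated:

* **blocked roving sequence** (adaptive sessions): consecutive blocks of
  four trials each contain every standard once, in random order; a trailing
  partial block is the prefix of one more permutation. Comparison
  directions are assigned 50/50 within each standard across the session.
* **balanced factorial design** (model simulations): every
  (standard × direction × Δd) cell equally often, shuffled. The default Δd
  grid is 21 equally spaced values from 0.05 to 0.60 — the adaptive
  procedure's floor and starting value — giving 4 × 2 × 21 × 5 = 840 trials.
  The grid is a package choice: any grid spanning the psychometric range
  works, and it is exposed in the run configuration.

## Observers

Sensory front end (all models): `x = ln d + ε`, `ε ~ N(0, σ_m²)`.

**Kalman filter.** Prior `N(μ_p, σ_p²)` over log duration with process
variance `q` (the prior's assumed random drift between observations; it
keeps the gain from collapsing). Per observation:
`k = (σ_p² + q)/(σ_p² + q + σ_m²)`, `μ_p ← (1−k)μ_p + k·x`, `σ_p² ← k·σ_m²`.
Both intervals update the prior; the response is "longer" iff the posterior
mean after C exceeds the posterior mean after S. With constant σ_m² the
gain converges to the positive root of `σ_m² k² + q k − q = 0`
(`steady_state_gain`), and with `q = 0` the recursion is exactly conjugate
Gaussian updating — both used as closed-form oracles in the tests.

**IRM1 / IRM2.** Internal reference `I ← g·I + (1−g)·x`, `0 ≤ g < 1`. The
update is sometimes written with a weight of (g−1) on the new observation;
taken literally that recursion diverges, so the package uses the standard
exponentially-weighted-moving-average form (1−g), the only reading
consistent with a geometric moving average and with the `k = 1−g`
correspondence to the Kalman gain. IRM1 updates the reference with the
standard only and compares the raw comparison observation against it; IRM2
updates with both intervals and compares the reference after each update.
The IRM reference after n updates equals the closed-form EWMA expansion
`(1−g)·Σ gʲ·x_{n−j} + gⁿ·I₀` (third oracle).

**Initialization.** Priors and references start at ln(0.849), the log
geometric mean of the standards — a neutral start at the distribution
center; the Kalman prior variance starts at `σ_m² + q` (a one-step
stationary guess). Only the first few trials are sensitive to this choice;
at `q = 0.9` the gain reaches its fixed point within a handful of updates.

**Decision ties.** Exact ties between the two representations have zero
probability under continuous noise; they are broken by a fair coin so that
degenerate noiseless tests stay unbiased.

## Parameter defaults

| parameter | default | units | role |
|---|---|---|---|
| `q` | 0.9 | (log-s)² | Kalman process variance; fixed, not fitted |
| `g` | 0.15 | — | IRM weight on the previous reference |
| `sigma_m_mean` | 0.2 | log-s | location parameter of the σ_m,i population |
| `sigma_m_spread` | 0.25 | log-s | scale of the truncated normal |
| `sigma_m_bounds` | [0.25, ∞) | log-s | truncation of the σ_m,i population |
| staircase start / step / floor | 0.6 / 0.05 / 0.05 | Δd | 3-down/1-up rule |
| exclusion threshold | 1.0 | Δd | sessions exceeding it are flagged |

`q = 0.9` and `g = 0.15` are the fixed constants of the model-comparison
study; they are exposed in `RunConfig` but deliberately not optimized.
The per-subject sensory noise σ_m,i is drawn from a normal with location
0.2 truncated below. The spread and lower bound are the one genuinely free
choice in the population model, and they were calibrated jointly against
two externally fixed anchors of the comparison study: the population's
average per-update Kalman gain should sit near 0.85 (so that the Kalman
and IRM weightings are comparable via `k = 1−g`), and the Kalman
population's precision–bias Spearman correlation should fall in its
reference band around −0.89. A wide, low-bounded population (e.g. spread
0.2, bound 0.05) overshoots the gain (≈0.91) because very precise subjects
pile up at gains near 1; the adopted population (spread 0.25, bound 0.25)
meets both anchors. The calibration was done once, at the population
level, and is not revisited per run.

## Analysis stack

Responses are modelled with binomial probit regressions
(statsmodels GLM). Regressors are built within subject only; rows missing
a required lag (session starts) are dropped listwise per predictor set.

* **Pooled signature fit** (`delta_d_signed`, `s_centered`, `s_prev1`,
  `dd_prev1`): used for the qualitative model signatures. The previous
  comparison enters as the *signed Δd* of trial n−1 rather than its raw
  duration, to avoid collinearity with the previous standard.
  `prev_accuracy` (the previous trial's feedback code) is deliberately
  **excluded** here: the simulated observers ignore feedback, and previous
  accuracy is a function of the previous trial's noise and difficulty, so
  conditioning on it (a collider) manufactures a spurious
  previous-comparison effect even in IRM1, whose state provably never
  contains the comparison.
* **Per-subject fits** (`delta_d_signed`, `s_centered`, their interaction,
  `prev_accuracy`, `s_prev1`, `dd_prev1`, `s_prev2`): the full
  fixed-effect set, fitted to each subject's 840 trials. Each subject is
  summarized by **precision** (the `delta_d_signed` slope) and **bias**
  expressed as a *constant error*: the `s_centered` coefficient divided by
  the slope, i.e. the PSE shift per unit of centered log standard. The
  division matters: the raw `s_centered` coefficient scales with the
  subject's overall sensitivity, so for fixed-`g` IRM observers it is
  mechanically proportional to the slope and would show a strong *positive*
  precision–bias correlation that reflects scaling, not context weighting.
  The constant error removes that scale and isolates the weight the
  observer puts on its reference — constant (`g`) for the IRMs,
  precision-dependent (`1−k(σ_m)`) for the Kalman filter.
* **PSE**: the comparison duration at which the fitted P("longer") crosses
  one half, obtained by solving the linear predictor for the signed Δd and
  mapping back through the comparison-duration formulas.
* **Model evidence**: BIC = −2·logL + p·ln n per fit, compared through
  `BF01 = exp(ΔBIC10/2)`.
* **Correlations**: Spearman ρ (average ranks for ties) with a plain
  Fisher-z interval, `tanh(atanh ρ ± 1.96/√(n−3))`; at n = 200 and
  ρ = −0.89 this gives [−0.92, −0.86], the benchmark for the construction.
* Per-subject fits that fail (perfect separation, too few trials) are
  flagged non-converged and dropped with a logged count; a pooled fit on
  degenerate smoke-scale input degrades to a non-converged placeholder
  rather than aborting the pipeline.

Mixed-effects (GLMM) machinery is intentionally out of scope: the
simulation claims rest on per-subject GLMs plus aggregation, which is also
the route used for the headline precision–bias correlation.

## Adaptive staircase

Transformed 3-down/1-up rule: Δd decreases by one step after three
consecutive correct responses and increases after every error, converging
to the accuracy where up- and down-steps balance, 0.5^(1/3) ≈ 79.4 %
correct. The consecutive-correct counter resets on every error and every
down-step (the standard convention). There is no upper clamp; sessions
whose Δd exceeds 1 at any point are *flagged* for exclusion post hoc but
still completed and recorded — exclusion bounds the analysis, not the
procedure. Staircase validity is checked against a stationary synthetic
observer with a known probit psychometric function (labelled as such in
the code): the staircase settles at its 79.4 %-correct Δd and long-run
accuracy stays within a few points of the convergence level.

## Problem sizes and determinism

Default runs use 200 subjects × 840 fixed-design trials per model (the
study scale); the test suite additionally uses 2 000-trial staircase
sessions, 5 000-trial parameter-recovery fits, and replicate seeds 1–5 for
the correlation band. One master seed drives everything; per-subject
streams are spawned from it (`numpy` SeedSequence), so adding subjects
never reshuffles earlier ones, and identical configurations reproduce
outputs bit-for-bit. Record CSVs round-trip floats at 12 significant
digits.

## What the generator does and does not emulate

Emulated: the roving-standard blocked design, the comparison-duration
rules, the staircase with its exclusion rule, between-subject precision
variability, and the sequential state carried by each observer.

Not emulated: lapses and attention fluctuations, response keys/latencies,
feedback *use* (the observers never learn from feedback; the feedback code
is recorded only as an analysis regressor), chronometric counting
strategies (which in humans can break the scalar property for
multi-second durations), stimulus modality, and practice/warm-up effects.
Passing tests therefore validate the models' internal logic and the
analysis pipeline on data that satisfy the models' own assumptions; they
do not by themselves establish how human observers behave.

## Known limitations

* The precision–bias correlation band is sensitive to the σ_m,i population
  shape, which real datasets would pin down empirically; the package
  calibrates it once against the two anchors above.
* The pooled probit treats trials as independent within the fit; standard
  errors on pooled coefficients ignore subject-level clustering (the
  per-subject route is used wherever that matters).
* IRM2's and the Kalman filter's previous-comparison effects are of
  similar magnitude by construction; the package does not attempt to
  estimate the relative weighting of first vs second interval.
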