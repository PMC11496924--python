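# stepbandit

A tested simulator of an adaptive text-messaging physical-activity trial for
adults living with diabetes and elevated depressive symptoms, and the
statistical machinery to evaluate it. The package is for methodologists who
want to study — without access to any trial data — how a Thompson-sampling
contextual bandit that personalises daily message *category* and *timing*
compares against random messaging and a minimal-contact control, and how a
random-intercept linear mixed model summarises the resulting 24-week step
trajectories.

## What is inside

* **`stepbandit.messages`** — bilingual (English/Spanish) banks of feedback
  messages (5 categories, including "no feedback") and COM-B-based
  motivational messages (capability / motivation / opportunity / none), plus
  a weekly mood check. Within a category, texts are drawn uniformly; the
  policies personalise only category and timing.
* **`stepbandit.bandit`** — a factored Thompson-sampling bandit: three
  Bayesian linear regressions (feedback category, motivational category,
  delivery slot within 8 AM-8 PM) share one context vector (demographics,
  baseline depression score, language, trailing step history, previous
  action) and predict the standardised next-day step count. A symmetric
  zero-mean prior makes the cold start exactly uniform.
* **`stepbandit.cohort`** — the synthetic cohort: Gaussian random intercepts
  with very large between-person variance, arm-specific secular drift or
  heterogeneous per-category message responsiveness, AR(1)-capable daily
  noise floored at zero, and arm-specific missing-day burdens (MCAR by
  default, optional burst gaps).
* **`stepbandit.trial`** — stratified permuted-block randomisation (block
  size 3, 1:1:1, by language), the causally ordered day loop for all three
  arms, and the analysis-set quality filters (no data / fewer than 28
  observed days / more than 25% of observed days above 20,000 steps).
* **`stepbandit.lmm`** — the evaluation model, in statsmodels style: a
  `StepTrajectoryLMM` model whose `fit()` (REML via profile likelihood over
  the variance ratio) returns a `StepTrajectoryResults` with estimates,
  Wald intervals, a `summary()` table, trajectory projections and plots.
* **`stepbandit.pipeline` / `stepbandit.cli`** — config files, seed
  management, CSV surfaces and the `stepbandit` command
  (`simulate`, `analyze`, `report`, `run`).

## The model at the core

For participant $i$ on study day $t \in \{0,\dots,167\}$ with observed
daily step count $y_{it}$:

$$y_{it} = \beta_0 + \beta_C C_i + \beta_R R_i
  + (\beta_d + \beta_{Cd} C_i + \beta_{Rd} R_i)\,t + b_i + \varepsilon_{it},$$

with $C_i, R_i$ indicating the control and random arms (adaptive arm is the
reference), random intercept $b_i \sim N(0, \sigma_b^2)$ and residual
$\varepsilon_{it} \sim N(0, \sigma_e^2)$. From a fit, per-arm trajectory
projections are pure arithmetic: baseline $=$ day-1 mean, slope in
steps/day, gain $=$ slope $\times$ horizon (168 days), and percent change
$= 100 \times$ gain / baseline.

The bandit's reward model is a conjugate Bayesian linear regression per
decision dimension over [context $\times$ action one-hot] interactions;
rewards are next-day step counts z-scored against the participant's
trailing 28-day statistics and clipped to $\pm 5$.

## Worked example

```python
import numpy as np
import stepbandit as sb

cfg = sb.SimConfig(seed=42)            # 168 participants, 57/56/55 arms
profiles = sb.generate_cohort(cfg)
rng = np.random.default_rng(7)
log = sb.simulate_step_log(profiles, cfg.n_days, rng)   # drift-mode trial
analysis, excluded = sb.apply_quality_filters(log)
fit = sb.fit_lmm(analysis)
print(fit.summary())
```

prints

```
Random-intercept linear mixed model of daily step count
method: REML    observations: 24876    participants: 168
sigma_b^2 (between-person): 4,361,934.88    sigma_e^2 (residual): 2,624,967.77
log-likelihood: -219534.33    converged: True

parameter         estimate        se      ci_low     ci_high        p
intercept          3749.49    283.78     3193.28     4305.70 7.44e-40
control             341.70    397.94     -438.24     1121.64    0.391
random              628.12    399.60     -155.09     1411.32    0.116
day                   3.31      0.36        2.60        4.02  6.9e-20
control:day          -2.95      0.52       -3.96       -1.93 1.44e-08
random:day           -2.74      0.52       -3.75       -1.73  1.1e-07

Projected trajectories (horizon 168 days):
  adaptive  baseline    3749  slope   3.31/day  gain    556  change  14.8%
  control   baseline    4091  slope   0.37/day  gain     61  change   1.5%
  random    baseline    4378  slope   0.57/day  gain     96  change   2.2%
```

Reading this: the adaptive arm was generated with a latent drift of 3.61
steps/day; this replicate's REML estimate is 3.31 (95% CI 2.60-4.02) —
day-to-day noise with SD ~1700 steps and between-person SD ~2300 steps make
single-trial slope estimates this uncertain, which is exactly what the
simulator is for. The gain column is slope x 168 and the change column is
the gain relative to the model's day-1 baseline.

The same run from a shell:

```bash
stepbandit run --seed 42 --out out/
stepbandit report --steps out/step_log.csv --plot out/trajectories.png
```

To watch the bandit itself learn, switch the cohort to
`effect_mode="responsive"` with non-zero `effect_means` and run
`sb.run_trial(...)`; the decision log records every category/slot choice,
whether its next-day reward was observed, and the raw next-day count.

## Documentation

`docs/methods.md` describes the generative model, the bandit's reward
model and priors, the estimation algorithm, all default parameters and
their provenance, and known limitations.
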