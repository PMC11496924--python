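# Methods

## Overview

`stepbandit` simulates a 24-week (168-day), three-arm randomized trial of
daily adaptive text messaging for physical activity and evaluates it with a
random-intercept linear mixed model (LMM). Everything is synthetic: the
package's purpose is to make the decision algorithm and the evaluation
pipeline testable end to end, including parameter-recovery studies at
realistic scale.

## Generative model of daily steps

For participant $i$ with arm $a(i)$, day $t \in \{0,\dots,167\}$:

* random intercept $b_i \sim N(\mu_{a(i)}, \sigma_b^2)$, re-drawn while
  negative;
* latent mean $m_{it} = b_i + \delta_{a(i)} t + \theta_i[\text{action}]$,
  where $\delta$ is the arm's secular drift and
  $\theta_i$ the person's additive per-category message effects (the
  action credited to day $t$ is the message sent on the morning of day
  $t-1$; no message and category code 0 contribute nothing);
* noise $\varepsilon_{it}$ is stationary AR(1) with marginal SD
  $\sigma_e$ and correlation $\rho$;
* observed count $y_{it} = \max(0, \text{round}(m_{it} +
  \varepsilon_{it}))$;
* each day is unobserved ("transmission gap") with arm-specific
  probability; by default missing completely at random, optionally in
  geometric bursts whose start rate is scaled to preserve the expected
  missing-day burden.

### Default parameters and their provenance

| parameter | default | units | rationale |
|---|---|---|---|
| participants | 168 (57/56/55 control/random/adaptive) | — | emulated trial's analytic sample |
| days | 168 | — | 24-week intervention |
| arm day-1 means | 3480.11 / 3697.71 / 3196.79 | steps | fitted arm baselines of the emulated trial |
| $\sigma_b^2$ | 5,419,080.25 | steps² | reported random-intercept variance |
| $\sigma_e$ | 1718 | steps | calibrated so the day-1 cross-sectional SD $\sqrt{\sigma_b^2+\sigma_e^2}\approx 2890$ matches the observed per-arm day-1 SDs (~2250-3275) |
| $\rho$ (AR1) | 0 | — | the evaluation model assumes exchangeable residuals; the generator's default is the simplest process consistent with it. $\rho>0$ is a sensitivity knob |
| arm drifts | 3.61 / 0.81 / 0.35 | steps/day | adaptive/control/random trajectory slopes being emulated (drift mode) |
| missing days | 26 / 20 / 14 per arm | days of 168 | reported arm-level missing-day means (~12% overall) |
| language split | 24% Spanish | — | cohort marginal |
| clinic recruitment | 37.5% | — | cohort marginal |
| responsiveness $\theta_i$ (responsive mode) | $N(\text{mean}, 150)$, clipped to $\pm 500$ | steps/day | effect heterogeneity large enough to be discoverable at trial scale but small against daily noise |

Two effect modes exist because they serve different tests. **Drift mode**
(default) imposes the arm trends directly and zeroes $\theta_i$; it makes
LMM parameter recovery well-defined. **Responsive mode** zeroes the drifts'
role as ground truth and lets arm differences emerge from $\theta_i$ plus
bandit learning; it is used to study the policy itself.

### What the generator does *not* emulate

Real pedometer streams have day-of-week structure, weather and season
effects, heavy-tailed and zero-inflated counts, informative missingness
(phones stay closed on inactive days), measurement heterogeneity across
devices, and behavioural habituation to repeated messages. Passing tests
therefore demonstrate correctness of the algorithms under the stated
stochastic model, not effectiveness of messaging in any real population.

## The decision policy

Each morning the adaptive arm's policy picks a feedback category (5), a
motivational category (4) and a delivery slot (4 windows, 8 AM-8 PM).
Selection is Thompson sampling over three *factored* Bayesian linear
regressions — one per decision dimension, sharing the context — rather
than one 80-arm joint bandit; at ~55 adaptive participants the factored
model is far more sample-efficient. The model is pooled across
participants, with person-level covariates in the context.

* Context vector (22 features): intercept; standardised age and PHQ-8;
  sex and language codes; z-scored previous-day steps and trailing 7-day
  mean (against reference level 3200 / scale 2900 steps);
  missing-yesterday flag; day/168; one-hot of the previous day's action
  (5+4+4). A minimal intercept-only encoder exists for small planted-effect
  studies.
* Reward: next-day step count z-scored against the participant's trailing
  28-day observed mean/SD, clipped to $\pm 5$; with fewer than two recent
  observations the reference scale is used. Standardisation keeps
  high-baseline walkers from dominating the pooled regression.
* Prior: zero-mean, isotropic, unit scale on the interaction design, fixed
  reward noise $\sigma_r^2 = 1$. The symmetric prior forces the cold start
  to be uniform over each dimension's actions, which is exactly the
  "random first message" behaviour wanted; conjugacy gives closed-form
  sequential updates that provably equal the batch posterior.
* Missing next-day counts skip the update (no imputation); the decision is
  still logged. Argmax ties break uniformly with the run's RNG.
* Slot boundaries are the package's choice of four 3-hour windows
  ([8,11), [11,14), [14,17), [17,20) hours).

The control arm receives only the weekly mood message; the random arm draws
each action component independently and uniformly each day (its "no
message" design shares are therefore 20% for feedback and 25% for
motivation).

## Trial mechanics

Randomisation is permuted-block (size 3, 1:1:1) within language strata, so
imbalance never exceeds one per stratum. The day loop enforces causality:
decisions on day $t$ see data through $t-1$; the message sent on day $t$
affects the count on day $t+1$; posterior updates happen when that count
arrives. Mood messages go to all arms every 7th day; a reminder event is
logged the day after any transmission gap (no behavioural effect — the
package has no evidence to quantify one).

Analysis-set filters, applied independently per participant: zero observed
days; fewer than 28 observed days ("at least 28" is inclusive, so 28 is
retained); strictly more than 25% of *observed* days above 20,000 steps
(25.0% exactly is retained).

## Estimation

The LMM is fitted by REML profile likelihood over the variance ratio
$\gamma = \sigma_b^2/\sigma_e^2$. For fixed $\gamma$ the fixed effects are
closed-form GLS via per-participant sufficient statistics (Woodbury on the
compound-symmetric within-person covariance), and $\hat\sigma_e^2$ has a
closed form; the scalar profile objective is minimised by a coarse
log-grid followed by bounded Brent refinement, with the exact $\gamma = 0$
(OLS) limit checked so boundary solutions are exact. ML is available for
likelihood-ratio tests of nested fixed-effect structures
(`include_interactions=False` drops the arm-by-day terms). Confidence
intervals are Wald with normal quantiles — no Satterthwaite correction —
matching the symmetric intervals such models are typically reported with.
The implementation is cross-checked in the test suite against statsmodels
`MixedLM` on simulated data.

Numerical safeguards: the residual sum of squares is clamped at $10^{-12}$
so exactly-interpolating inputs (flat trajectories) remain finite; the
design is rank-checked up front; a singular subgroup fit returns its
exception without losing the other subgroups.

Projections satisfy the identities gain $=$ slope $\times$ horizon and
percent $= 100 \times$ gain / baseline exactly, with the horizon multiplier
168 (day-1 baseline, day coding 0-167). Report rounding: coefficients to 2
decimals, step totals to integers, percents to 1 decimal.

## Replicate studies and problem sizes

The recovery study (tests and `scripts/acceptance.py`) simulates 200
replicate trials at the default conditions in drift mode and refits each.
Because drift-mode message effects are identically zero, replicates use the
vectorised trajectory sampler rather than the full day loop — the step-log
distribution is identical, and the custom profile-REML fit keeps each
replicate in tens of milliseconds. The known systematic effect at these
settings is the zero floor on daily counts: participants whose intercepts
sit within a couple of residual SDs of zero have part of their latent
trajectory censored, which attenuates the recovered slope by roughly 5-7%
and shrinks the recovered intercept variance. The recovery test therefore
asserts the replicate-mean adaptive slope within 10% of the generating
3.61 steps/day, with 95% CI coverage required to land in [90%, 99%].

## Known limitations

* The floor/rounding censoring described above biases recovery of the
  *intercept-scale* quantities (arm offsets, $\sigma_b^2$) more strongly
  than the slopes; the generator is honest about producing non-negative
  integer counts rather than tuned to make every estimator unbiased.
* The deployed algorithm behind the emulated trial used a feature set,
  prior and update cadence that are not public; this package documents its
  own choices as defaults, not as a reconstruction.
* MCAR missingness is the default; the optional activity-dependent
  missingness mode is deliberately off because the emulated analysis treats
  gaps as transmission errors.
* No off-policy evaluation from real decision logs, no PHQ-8 trajectory
  modelling, no dropout process distinct from transmission gaps.
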