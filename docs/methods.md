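# Methods

This note records the model, its assumptions, the synthetic-data design
and the numerical choices, in enough detail to audit or extend the
package.

## State space and dynamics

States are subsets of {DM, CHD, stroke, CRC} crossed with a depression
flag, plus absorbing death — 33 states, ordered by number of conditions,
then lexicographically, not-depressed before depressed, DEAD last.  Onset
of a chronic condition is irreversible; depression is reversible.

Within each annual cycle, from any alive state: death competes first
(state-specific mortality); survivors acquire at most one new condition
(per-condition annual probabilities treated as competing risks; if their
sum ever exceeded the available mass they would be rescaled
proportionally — a guard that is never triggered at realistic inputs, and
is logged through a validation error otherwise); every alive destination
is then split between the depressed and not-depressed halves using the
destination state's predicted depression prevalence.  Depression is
therefore memoryless — reassigned each cycle from a prevalence, not
propagated as an incidence — which matches its role as an annually
measured prevalence and keeps it out of the mortality and incidence
pathways: depression affects only utilities and costs.

Cohorts enter entirely at risk, split across integer single years of age
by a truncated-normal entry-age distribution, and are stepped for 70
cycles.  Members completing the cycle in which they reach age 100 move to
an EXITED accounting bucket and accrue nothing further; occupancy plus
EXITED is conserved exactly.  Person-years use the half-cycle (trapezoid)
correction; cycle-`t` flows are mid-cycle quantities and discount by
`(1+r)^(t−0.5)`.

## Input models

All three families share the covariate schema (intercept, age centred at
50, female, quintile indicators with quintile 1 as reference; cost models
add a depressed indicator).

**Weibull PH.**  `H(a) = exp(xβ)·a^γ` on the attained-age time scale with
left truncation at entry to the risk set, so hazard ratios are `exp(β)`
and the annual transition probability from age `a` is
`1 − exp(−exp(xβ)(( a+1)^γ − a^γ))`.  Because attained age is the time
scale, the synthetic truth sets the age-at-entry covariate coefficient to
zero (an extra age covariate would double-count age); the fitter still
estimates it and recovers ≈0.  The custom maximum-likelihood fitter
optimises `(log γ, β)` with an analytic gradient and an
observed-information covariance.  Internally it rescales time by the
median observation age: with `H = exp(β₀)·a^γ` the intercept and shape
are nearly collinear (`β₀ ≈ −γ·log a̅ + c`), and optimising
`β₀′ = β₀ + γ·log a̅` with `log γ` bounded in [−4, 4] plus a small
multi-start over γ ∈ {1, 2, 5, 8} makes the fit reliable; the covariance
is mapped back through the Jacobian.  An independent cross-check against
a left-truncated Weibull AFT fitter (lifelines), converted through
`β_PH = −ρ·β_AFT`, agrees to ~1%.

**Logistic depression** and the **two-part cost model** (probit for any
cost; gamma GLM, log link, for positive costs) are fitted with
statsmodels; predicted mean cost is `Φ(xβ₁)·exp(xβ₂)`.

**Composition across condition subsets.**  Mortality, depression and cost
models are estimated per state class (healthy plus each single
condition); multi-condition states compose additively on the log scale:
`log H_D = log H_AR + Σ_d (log H_{d} − log H_AR)` for mortality (which is
again Weibull, with shape and coefficients composing additively), and the
same rule on the logit / probit-index / log-mean for depression and
costs.  Incidence hazards are taken to be independent of conditions
already present (the additive rule with zero increments); the registry
evidence behind state-specific incidence is not available, and this keeps
the truth transparent and recoverable.  Class-specific quintile
coefficients are preserved, so each class can carry its own deprivation
gradient.

**Parameter uncertainty.**  Each PSA draw is `mean + L·z` per model, `L`
the lower Cholesky factor of the model covariance (an eigen-decomposition
square root for exactly semi-definite matrices; indefinite matrices raise
an error naming the model).  `log γ` is treated as Gaussian and included.
Models are sampled independently (no cross-model covariance is
estimated).  Each of the PSA iterations uses one joint draw shared
between the intervention and control arms and both sexes — common random
parameters, so increments isolate the intervention effect.  The trial
odds ratio is drawn lognormally with log-mean log 1.42 and log-SD
(log 1.73 − log 1.17)/(2·1.96).

## Synthetic registry and survey

The generator emulates a UK primary-care cohort of ~210 000 healthy
adults.  Entry demographics (quintile shares, sex split per quintile,
mean entry ages ~49–54) follow the configured population table; the
entry-age *shape* is a truncated normal (SD 10 years, bounds 18–90) — a
stand-in, since only means are configured.  Event histories are simulated
exactly from the truth by sequential competing-risks inversion on the age
scale: conditional on being event-free at age `a`, the next event age
solves `H(T) = H(a) + Exp(1)`; mortality scales are re-composed whenever
a condition is acquired.  Annual depression indicators and annual costs
(zero with probability `1 − Φ(xβ₁)`, else gamma with mean `exp(xβ₂)` and
shape 1.2) are drawn per person-year given the state at the start of the
year.  Default follow-up is 5 years.  Cohort sizes: 2×10⁵ mirrors the
emulated registry; a 10⁴ "fast" profile exists for demonstrations —
at that size the sparse single-condition classes cannot identify all
per-class coefficients, and the estimator falls back to carrying the
healthy-class gradients with a re-anchored intercept (logged); fits meant
for inference should use ≥10⁵.

The activity survey draws three-category activity per sex × 10-year band
(16–25 … 76+) × quintile.  The default distribution anchors the
age-standardised inactivity prevalences per sex and quintile at the
mid-age band with a linear age gradient (factor 0.70 + 0.10·band), while
the *active* (≥5 days/week) share varies by age only
(0.38 − 0.03·band): the deprivation gradient lives in the split between
inactive and insufficiently active, so combining those categories largely
removes the inequality — the pattern reported for the underlying survey
data.  No cluster-sampling design or survey weights are emulated.

What passing tests on these data do show: the full pipeline — generation,
estimation, matrix assembly, cohort dynamics, economics — is internally
consistent and recovers known truth.  What they do not show: that the
default baseline levels (incidence ~2–5/1000/yr at age 60, at-risk
mortality 4/1000 at 60 with Weibull shape 8, depression prevalence
8–18%, mean annual costs ~£350 at risk up to ~£1200+ with conditions,
utilities 0.74–0.92 with a 0.83 depression multiplier, WHO-style relative
risks 1.85–2.20 for inactivity) are calibrated to any particular real
population; they are realistic orders of magnitude chosen once and
documented in `pacea/configs/truth_default.yaml`.  Deprivation gradients
(hazard and odds ratios per quintile) are the configured study
conditions.

## Intervention model

The odds ratio applies to the binary split active vs not-active (the
source trial outcome); the gain in the active share is removed from the
inactive and insufficient categories in proportion to their sizes.  The
shift happens once at baseline and is sustained for the 5-year effect
period, then switches off abruptly.  The PIF is computed per sex ×
age-band × quintile stratum; the multiplier applies to the at-risk
incidence *probabilities* (for annual probabilities of a few per 1000 the
difference from scaling hazards is second order).  Attenuation `a` in a
quintile rescales the effect: `m′ = 1 − (1−a)(1−m)`.  The delivery cost
is charged per alive at-risk person-year during effect years — £35 for
the not-sufficiently-active share and 20% of £35 for the active share,
using the *baseline* (unshifted) distribution, since the cost split
reflects the observed population distribution; a per-quintile cost
multiplier implements the doubled-cost scenario.

## Economics

State utilities combine multiplicatively relative to the healthy
baseline, `u(D) = u_AR·Π_d (u_d/u_AR)`, times a depression multiplier;
DEAD is 0.  Costs always discount at 3.5%; only the QALY rate switches to
1.5% in the sensitivity analysis.  The 95% ranges are equal-tailed
2.5–97.5 percentiles of the simulation distribution.  The CEAC grid is
£0–£50 000 in £1 000 steps, and the probability cost-effective at λ
equals the fraction of simulations with positive NHB(λ) exactly, by
construction.  Per-sex runs (the model is run separately by sex) are
pooled by each sex's share of entrants within the quintile.  Failed PSA
draws (e.g. non-finite flows under extreme sampled parameters) are
logged and re-drawn from spare seeds, never silently dropped.

## Problem sizes and determinism

The test suite uses 200 PSA draws per quintile for the equity-ordering
check, 10⁵ individuals for the microsimulation oracle and 20 repetitions
of n = 10⁵ registries for parameter recovery; the analysis scripts
default to 200 draws (2000 reproduces the full-uncertainty run) and a
2×10⁵ registry.  All randomness flows through seeded
`numpy.random.Generator` hierarchies (`SeedSequence.spawn` per PSA
iteration), so every stage is exactly reproducible for a fixed seed.

## Known limitations

No individual-level memory (time since diagnosis), tunnel states or
remission; no intervention effect on depression or mortality beyond the
incidence pathway; no dose–response or intensity dimension; no
secondary-prevention use; direct health-service costs only; no
cross-model covariance; utilities do not vary by deprivation.  The
equity-ordering result is a property of the configured gradients plus
the activity distribution, not an empirical claim about any specific
population.
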