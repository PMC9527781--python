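# Methods

## The estimand

Working life expectancy (WLE) at age 50 is the expected number of years
spent in paid employment between ages 50 and 66, conditional on being
employed at 50; working years lost (WYL) are the expected years in each
non-employment destination over the same window, split into involuntary
exit (unemployment, disability benefits), voluntary exit (economic
inactivity, early retirement) and death. By construction
WLE + WYL_involuntary + WYL_voluntary + WYL_mortality = 16 years; the
implementation preserves this identity to floating-point precision and
the test suite asserts it at 1e-6.

## Model and estimation

**State space.** Four states on a monthly grid — employment (1),
involuntary exit (2), voluntary exit (3), death (4) — with nine allowed
transitions: all moves among the three living states plus each into
death, which is absorbing. The process is assumed Markov given age and
baseline covariates (intensities depend on the current state and age
only, not on duration in state or prior history).

**Episodes.** Each maximal run of months in a non-absorbing state is
one spell, at risk for up to three competing transitions, with delayed
entry at the spell's first month. A transition observed between months
m and m+1 is dated at age (m+1)/12 — register-style monthly data are
treated as exactly observed at the month boundary rather than
interval-censored. Observation is administratively censored at age 66
and at the end of follow-up. Ages are held as integer months internally
and exposed as years = months/12, so the monthly grid carries no
floating drift.

**Hazards.** One Cox proportional hazards model per transition, with
age as the time variable (clock forward) and left truncation handled
through the risk sets. Coefficients are maximised with
`lifelines.CoxPHFitter` (convergence tightened to 1e-9; a
non-convergent transition raises an error naming it). Ties — heavy on
a monthly grid — use the Breslow convention, so the baseline cumulative
hazard has the closed form dA₀(u) = d(u) / Σ_{at risk} exp(βᵀx_i),
which the package computes directly on the month grid; with no
covariates this is exactly the Nelson–Aalen estimator, and the tests
verify the equality against lifelines' independent Nelson–Aalen
implementation. Per-transition fitting (separate baselines and
coefficients, no effect sharing across transitions) is the
least-restrictive choice. A covariate constant across a transition's
risk rows is unidentifiable there and is dropped with a warning (its
log-HR treated as 0); a transition with zero events gets a zero hazard
plus a warning rather than a failure, so downstream occupancy always
computes.

**Occupancy and ELOS.** Predicted cumulative-hazard step functions at a
covariate profile (baseline jumps scaled by exp(βᵀx)) enter the
Aalen–Johansen product integral over the pooled jump ages. Should a
row's increments at one age sum above 1 (possible in sparse strata),
the row is rescaled to total mass 1 and the event counted and warned
about, keeping every factor stochastic. P(s,·) is piecewise constant
between jumps and right-continuous, so the ELOS integral is an exact
step-function sum — the convention under which the estimator reproduces
brute-force occupancy counting exactly on uncensored data (verified to
1e-10 in the tests).

**Stratified reports.** Stratum-specific WLE/WYL rows are produced by
default as covariate-profile predictions from one pooled fit (the
stratification variables, any exposure flag, and adjustment covariates
enter the model; each row is the occupancy at that stratum's profile
with adjustment covariates at reference). This keeps sparse strata
estimable and makes the disease/education gradients interpretable as
model effects; subgroup refits can be had by subsetting the cohort and
calling the pipeline directly. Gender adjustment is applied to the
working-condition analyses (which are not gender-stratified) by keeping
`female` in the model and predicting at its reference level.

**Bootstrap.** Percentile intervals from n-out-of-n person-level
resampling: each replicate redraws persons with replacement, keeps
whole timelines intact (episode-level resampling would break
within-person dependence), re-runs episodes → fits → occupancy, and the
2.5th/97.5th percentiles of the replicate distribution bound the 95%
interval. One master `SeedSequence` spawns an independent substream per
replicate, so results are bit-identical under a fixed seed and
replicates are reproducible in isolation. Replicates whose fit fails
outright are logged and excluded from the percentiles; an all-failed
bootstrap raises.

## Cohort rules and questionnaire machinery

**Working conditions.** Five scales with 5/4/5/3/4 items (physical
workload, job demands, autonomy, emotional demands, social support),
each item answered 1='always' … 5='(almost) never'. Demand items are
recoded 6−response so a higher sum score is always worse; autonomy and
social support already point that way. Which specific items are
reversed is configurable per item; the defaults reverse all items of
the three demand scales and none of the two resource scales. A scale
with any missing item is scored missing (no imputation); a respondent
is retained if at least one scale is complete. Adverse exposure is a
sum score strictly above the sample's 75th percentile (linear
interpolation between order statistics), computed once on the full
analysis sample, not per stratum; ties at the threshold fall in the
referent group. With ties or small samples the exposed fraction can
exceed 25% by at most the tie mass plus one observation.

**Chronic disease.** Six major conditions (diabetes, cardiovascular,
digestive, psychological, musculoskeletal, respiratory) define the
disease group; respondents reporting none of the checklist conditions
are the disease-free group; respondents reporting only minor conditions
(migraine, skin, hearing or eye problems, epilepsy, life-threatening or
other unknown disease) are excluded. The package vocabulary is these 13
labels; the original checklist offered 15 options, but only these are
named, so the two remainder options are folded into "other".

**Inclusion.** Drop the self-employed, then respondents with no
complete working-condition scale, then the disease-rule exclusions;
truncate timelines to [50, 66) — a respondent first observed at 48
enters the analysis at exactly 50 — and drop anyone never observed
inside the window. Each step's counts are logged and written to
`cohort.log`.

## The synthetic-data generator

The generator emulates the structure the analysis assumes: covariates
drawn hierarchically (education → disease | education → gender and five
exposure flags | education × disease) with default prevalences taken
from a published 11,800-person Dutch cohort table (education mix
27/39/34%, disease 58/54/49% by education, exposure cells such as 42%
high physical workload among low-educated diseased workers); then
continuous-time Markov trajectories with intensities
rate_hj(age)·exp(βᵀx), simulated exactly (exponential waiting times,
re-drawn at piecewise-constant age knots) and discretized by recording
the state at each month boundary. Because the underlying process is
simulated in continuous time, a time-homogeneous configuration has an
exact matrix-exponential oracle: occupancy rows of exp((t−s)Q) and
ELOS from the top-right block of exp(T·[[Q, I], [0, 0]]), against which
the pipeline's estimates are compared (a fine-grid forward-Euler solver
provides a second, independent numerical check in the tests).

Scenario defaults:

- **Default ("paper-like") scenario** — entry ages uniform over 48–60
  (so some persons turn 50 during follow-up, exercising delayed entry),
  98 months of follow-up, involuntary-exit hazard 0.012/yr at reference
  raised by disease (log-HR 0.65), low education, female gender and
  adverse exposures (largest for low social support, 0.55); voluntary
  exit 0.008/yr jumping to 0.13/yr after 60 (retirement); mortality
  calibrated so about 2.7% of the cohort dies over follow-up. Baseline
  magnitudes are order-of-magnitude choices for a 50–66 workforce and
  are not claimed to reproduce any published point estimate; the
  scenario is built to reproduce the qualitative structure (more
  involuntary WYL with disease in every education stratum, voluntary
  WYL nearly flat).
- **Recovery scenario** — time-homogeneous 4-state rates with a known
  disease log-HR of 0.5 into involuntary exit and −0.3 on re-entry.
  Everyone enters at exactly 50 and is followed to 66: with staggered
  entry the early risk sets in the non-employment states are tiny and
  the Monte-Carlo SD of the recovered WLE at n=5000 is ~0.17 years;
  with common entry it is ~0.06 years, which is what a recovery
  benchmark should measure. Delayed entry is exercised by the default
  scenario and by dedicated risk-set tests instead.
- **Two-state scenario** — a single absorbing exit at 0.1/yr from age
  50, whose WLE has the closed form (1−e^{−1.6})/0.1 = 7.981 years.

Exposure flags are drawn directly per cell prevalence (their marginals
land near 25% because the source table's cells do) and raw items are
synthesised in disjoint recoded ranges (4–5 exposed, 1–3 otherwise), so
written cohorts carry the full persons-file schema. A cohort read back
from CSV re-derives exposure through the quartile machinery, which can
reclassify a small tail whenever the marginal prevalence is not exactly
25%; in-memory simulated cohorts keep the generator's flags, which are
the simulation truth.

What the generator does *not* emulate: item-level response
distributions beyond the sum-score split, duration-dependent
(non-Markov) transition intensities, survey weighting, seasonal or
calendar-time effects, and informative censoring. Passing tests
therefore show the estimator is correct under the model's own
assumptions at realistic prevalences — not that those assumptions hold
in any particular register cohort.

## Numerical choices and problem sizes

- Event ages live on the integer month grid; cumulative hazards are
  step functions with jumps at months only.
- Cox convergence: lifelines Newton iterations at precision 1e-9;
  Breslow ties throughout (Efron would differ slightly on this grid;
  the replication-invariance test tolerances of 1e-4 reflect the
  fitter's iterative stopping rule, not the estimator).
- Aalen–Johansen stochasticity guard: per-age row mass capped at 1
  with a warning counter on the returned grid.
- Validation sizes (chosen to keep the whole battery within a few
  minutes on one CPU): counting-oracle equivalence at n=50 uncensored
  persons; closed-form two-state recovery at n=20,000 (tolerance 0.1
  years, covering the ~0.03-year half-month discretization bias plus
  Monte-Carlo noise); coefficient/WLE recovery at n=5,000 (tolerances
  0.1 on log-HRs, 0.15 years on WLE); bootstrap coverage over 200
  repetitions of n=1,000 cohorts with B=200 replicates (nominal 95%,
  accepted band 88–99%); stratified pattern at n=10,000 without
  bootstrap.

## Known limitations

- Sickness absence is invisible in income-register-style states:
  workers on sick pay count as employed, so involuntary WYL is
  understated relative to designs that track long-term sickness.
- The Markov assumption ignores duration effects (e.g. benefit
  expiry); clock-reset models are out of scope.
- Proportional hazards are assumed per transition; no formal
  proportionality test is run.
- Profile prediction attributes stratum differences entirely to the
  modelled covariates; genuinely stratum-specific baselines require
  subgroup refits.
- Transitions into death are rare at these ages, so mortality-WYL
  estimates are the least stable — their bootstrap intervals are wide,
  matching the behaviour of the real-data analyses this mirrors.
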