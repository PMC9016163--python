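# Methods

## Model structure

The simulator advances a closed cohort — no births, deaths, migration or
other exits — through 10 discrete life stages with fixed age bands: 0–1,
2–5, 6–12, 13–17, 18–24, 25–29, 30–39, 40–49, 50–59, 60–65 years. Stages
with `age_low ≥ 18` are adult stages; smoking, alcohol use, marriage and
T2DM exist only there. Within each stage an agent's age is drawn uniformly
from the band.

Every time-varying quantity is updated by one equation per (variable,
stage): binary variables by logistic regression inverted through the expit
and a Bernoulli draw, BMI by a linear equation with Gaussian noise.
Behaviors depend only on lag-1 state (their own previous value, the
time-invariant socio-demographics, and for diet/activity the neighborhood
food/activity environment), so their within-stage evaluation order is
immaterial; BMI then sees the current-stage behaviors plus lagged BMI; T2DM
sees current BMI and behaviors. T2DM is treated as a diagnosis — absorbing —
because the incidence measures count first-time diagnoses; obesity status is
not absorbing, since BMI is continuous and can fall.

Two modelling choices were genuinely open and resolved as follows:

- **T2DM uses current-stage BMI**, not lagged BMI (lagged dependence is
  reserved for BMI's own equation). This is configurable through the
  coefficient table (`lag` column).
- **Child/adult classification dispatches at age 18**, not 19, so the
  weight-status rule boundary coincides with the adult-stage boundary. Both
  child-cutoff conventions (to 18 or 19) appear in practice; aligning with
  the stage structure avoids agents switching rules mid-stage.
- **Marital status** is drawn independently per adult stage from a
  stage-specific probability rather than modeled with lagged dynamics; no
  dynamic rule beyond the 18+ constraint is specified anywhere, and marriage
  only enters as a covariate.

## Randomness

All draws come from numpy `Generator` streams keyed by
`(seed, replicate, key)` with key 0 = neighborhoods, 1 = stage-0 agents,
100+t = stage-t advancement. Consequences:

- runs are bit-reproducible for a fixed (seed, replicate);
- results are independent of agent iteration order (states are sorted by
  agent id before vectorized draws);
- a single stage can be re-simulated from a frozen panel with exactly the
  stream a full run would consume — this gives common random numbers (CRN)
  across calibration grid points and across paired intervention/natural
  runs, so a null intervention contrasts to exactly zero;
- the draw count per equation never depends on coefficient values or
  interventions, keeping paired runs aligned.

## Synthetic default parameter set

The shipped default emulates a diverse urban county cohort. Coefficients
are invented but sign-constrained by the model's causal structure:
sugary-drink and fast-food consumption raise BMI (+0.5 each), fruit and
vegetable intake (−0.3) and physical activity (−0.8) lower it, BMI raises
T2DM risk (+0.1 per kg/m² on the log-odds scale), and lag-1 BMI suppresses
activity (−0.04 per kg/m², the behavioral feedback). Neighborhood terms
enter only diet and activity equations (fast-food density → sugary drinks
and fast food; supermarket density → fruit/vegetables; walkability and park
access → activity), per the initialization/execution structure.

Designed stage trajectories (the study conditions the generator emulates):
fast-food and sugary-drink consumption high in childhood (~85% / ~70% at
ages 6–12) and declining with age; activity low, with an adolescent trough
(~20%); fruit/vegetable intake roughly constant (~0.42–0.55); ~20%
breastfed ≥ 6 months; adult mean BMI rising 25.5 → 29.0 kg/m²; per-stage
T2DM incidence among the undiagnosed rising from 1.2% at ages 18–24 to a
25% peak at 40–49 and easing afterwards. Intercepts are centred
analytically: for a logistic equation,
`β₀ = logit(p_t) − Σ βᵢ·E[xᵢ]` with the lag term evaluated at the previous
stage's designed level; for BMI, `β₀ = m_t − ρ·m_{t−1} − Σ βᵢ·E[xᵢ]` with
per-stage noise chosen to hold the designed cross-sectional SD
(`σ_t² = s_t² − ρ²·s_{t−1}²`, floored at 0.25). Because the expectation of
an expit is not the expit of the expectation, realized proportions deviate
slightly from the designs; calibration closes the gap when fidelity
matters.

Neighborhood socio-demographics are truncated normals: % non-White
mean 0.635 (SD 0.20), % below FPL mean 0.22 (SD 0.12), % bachelor+ mean
0.30 (SD 0.15). Agent race and income group are Bernoulli draws from their
neighborhood's proportions, sex is Bernoulli(0.5) (configurable; no sex
split is prescribed). Because race is inherited from only 235 neighborhood
draws, the cohort's non-White share varies across seeds with SD
≈ 0.20/√235 ≈ 0.013 — far more than the agent-level binomial SD; tests use
the clustered SD.

BMI values are clipped to [10, 80] kg/m² to prevent pathological feedback
excursions; neighborhood proportions are clipped to [0, 1] and densities to
≥ 0.

### Growth reference

The shipped LMS growth reference is **synthetic**: shaped like real
BMI-for-age references (infancy peak near 9 months, adiposity rebound at
5–6 years, rise through adolescence; L ∈ [−2.4, −0.5], S ∈ [0.08, 0.13])
but with invented values, tabulated every 3 months for ages 0–240 months
and both sexes, linearly interpolated in age. Users supply a real CDC/WHO
table in the same column layout for substantive work. Consequently the
default childhood obesity prevalence (~4–6%) is lower than a US urban
cohort's; the adult measures, which use fixed BMI cutoffs, are unaffected
by the reference.

### What passing tests show — and do not

The generator reproduces the structural features the engine is tested
against (adult-only behaviors, absorbing diagnosis, feedback, racial and
SES gradients, rising adult obesity, mid-life T2DM incidence peak). It does
not reproduce any real population's absolute levels, secular trends, cohort
effects, measurement error, or attrition — a closed cohort overestimates
occurrence measures by construction. Passing tests therefore validate the
machinery, not a forecast for any actual population.

## Measures

Risk windows select the stages whose age band lies inside the window; an
agent is at risk if not positive at the stage preceding window entry. The
adult obesity window (18–65) thereby re-enters agents whose childhood
obesity reverted by ages 13–17, while T2DM (structurally absent before 18)
has everyone at risk. Events accrue person-time from window entry to the
event stage's **midpoint** age; censored agents accrue the full window
width. The exact accrual rule behind the mirrored published table is not
stated, so simulated person-years are validated by property (bounds,
additivity) rather than against printed values. Cumulative incidence uses
the full stratum cohort as denominator (so events/total reproduces the
published cells), with binomial Wald 95% CIs; rates are per 1,000
person-years with Poisson Wald CIs (`±1.96·1000·√events/py`) — both
reproduce the published intervals at printed rounding, so no exact/score
intervals are offered. Age-specific incidence divides first events at a
stage by the count never positive before it; with an empty risk set it is
flagged undefined (NaN with a warning). Per-stage "annual" incidence rates
in trend reports divide by band person-time, not band width.

## Calibration

Calibration-in-the-large tunes intercepts so mean simulated values match
observed means/proportions per stage, objective = mean absolute error over
the stage's calibrated variables (all behaviors and outcomes applicable at
that stage). Stages are tuned birth-first and frozen; within a stage,
equations are tuned in evaluation order so BMI sees tuned behaviors and
T2DM a tuned BMI. Each tunable is searched on a 1-D grid — default 41
points over incumbent ± max(2, 2·noise_sd), one 5× refinement round (final
cell 1/40 of the half-range) — scoring each point as the mean over R
replicate re-simulations of the stage (default R = 3) with CRN across
points. Candidate sets always include the incumbent, so the stage MAE
cannot increase; exact ties break toward the smallest absolute value.

Grids are centred on the **incumbent** intercept rather than on the
link-transformed observed mean: for equations with lagged terms the
matching intercept is offset from `logit(p_obs)` by the covariate
contribution, and for BMI (`β₀ ≈ m_t − ρ·m_{t−1} − …`) the observed mean is
nowhere near the intercept, so observed-mean centring can exclude the
optimum entirely.

Feedback coefficients are tuned only when named explicitly
(`feedback=[("activity", "bmi", 1)]`, multiplier grid [0, 2]×initial, 21
points): a single mean target per (variable, stage) cannot separately
identify an intercept and a feedback slope, so joint tuning is opt-in and
sequence-configurable rather than default.

Parameter-recovery behavior: with targets simulated from a known generator
under the same seed convention, CRN makes recovery exact up to the grid's
resolution of the objective. For rare outcomes the finite-cohort MAE is
exactly flat over a small intercept interval (no Bernoulli draw flips), and
the tie-break then returns the flat region's edge — observationally
equivalent to the generating value (gap exactly 0) though numerically
different. R² between observed and simulated stage series is reported per
variable and flagged undefined below 3 paired points.

## Scenarios

Interventions override an exposure for chosen stages and an optional
subpopulation: `set` replaces the drawn value, `shift` adds to the Bernoulli
probability after link inversion (clipped to [0, 1]), `scale_coefficient`
multiplies a named term's coefficient before simulation. Both post-draw and
pre-draw forms are supported because "altering the exposure to a desired
level" is meaningful either way; `set` answers the sharper counterfactual.
Neighborhood-environment overrides edit the neighborhood table after
environment prediction. Contrasts (intervention − natural) are computed
cell-by-cell on measure tables and stage prevalences; uncertainty comes
from ≥ 20 paired replicate seeds (Monte-Carlo SD), since paired seeds remove
common noise. Time-invariant socio-demographics cannot be intervened on.

## Problem sizes and numerical notes

The full-scale default run (98,230 agents × 10 stages) takes a few seconds
on one CPU; tests mostly use 500-agent configurations, the
parameter-recovery check 10,000 agents × 3 replicates (a few minutes), and
directional checks 3 seeds at full scale — sizes chosen to make binomial
Monte-Carlo error (≈ √(p(1−p)/n)) small against the tolerances asserted.
The LMS z-score switches to its analytic `log(BMI/M)/S` limit for
|L| < 1e-7, where the power form loses all floating-point precision.
Weight-status boundaries are left-closed exactly as specified; BMI-at-median
scores z = 0 for any L, S.

## Known limitations

No mortality, migration, fertility or competing risks (closed cohort —
occurrence measures are overestimates); no social-network transmission of
behaviors; no within-stage event timing beyond the midpoint convention; the
synthetic growth reference and coefficient values are placeholders for
user-supplied evidence; external validation against a real longitudinal
cohort is out of scope by design.
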