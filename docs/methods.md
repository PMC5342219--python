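# Methods

`lcpm` is a person-level microsimulation of smoking and lung cancer in the
Chinese population, built to compare CT-screening eligibility policies (the
U.S. CMS rule and the Chinese national guideline, "CNG") on mortality
reduction, life-years saved and screening burden over 2016–2050.  This note
records the model, its assumptions, the calibration procedure, the numerical
choices, and what the synthetic stand-ins do and do not represent.

## Population and time

Closed birth cohorts enter at age 15 and exit (alive) at 85; tallies cover
calendar years 1975–2050, so birth cohorts 1891–2035 contribute.  Time is
discrete in whole years: a person's attained age in year *y* is *y − birth
year*, events are resolved once per year, and deaths are tallied in the year
they occur.  Cohorts already older than 15 in 1975 receive retrospectively
sampled life histories from the same generative model, which is what lets
1990s prevalence targets constrain cohorts born in the 1920s–1950s.

Each simulated cohort is scaled to the population projection at its entry
point (age 15, or its attained age in 1975); thereafter simulated
other-cause mortality governs attrition.  The projection is a synthetic
stand-in (below), so absolute population-scale outputs are in synthetic
units; within-model contrasts (policy vs baseline under common random
numbers) are the meaningful outputs.

## Smoking module

**Initiation.** P(initiated by age *a*) for a cohort born in year *c* is
`L(c) · logistic(k (a − a0))`.  The eventual ever-smoker level `L(c)` is
piecewise linear over six (male) / seven (female) birth-cohort knots and
held flat outside; `a0` and `k` are shared within sex.  All of these are
free parameters set by calibration.  The knot levels are a fitting device:
the prevalence anchors identify a ~40-cohort moving average of `L`, not its
pointwise values, so the fitted knot pattern should not be read
demographically.  `a0` is restricted to ages 16–26 and `k` to [0.2, 1.5]
during fitting, keeping initiation in late adolescence / young adulthood;
the cross-sectional anchors alone cannot identify the initiation-age
distribution, and pack-year accumulation — hence screening eligibility —
depends on it strongly.

**Cessation.** Current smokers quit with the published annual probabilities
(males: 0.02 at ages 30–65, 0.03 above 65; females: 0.02 from age 35), zero
below the tracked start ages.  No relapse.  A multiplier from a given
calendar year (default 2016) implements the cessation sensitivity analysis;
histories before that year are unchanged by construction because the
quit-survival curve is modified only at later ages.

A consequence worth stating plainly: reproducing a 1991 male current-smoker
prevalence of 0.66 under 2%/year one-way cessation from age 30 forces the
fitted male ever-smoker levels near 1.0 for pre-1950s cohorts.  That is
what the printed inputs jointly imply in any no-relapse model.

**Intensity.** Cigarettes/day is deterministic given (sex, age, year): the
male 2006 age profile (anchors at ages 37–74) carried across calendar time
by the pooled year trend (anchors 1980/1996/2006/2012, normalized at 2006),
with female intensity equal to the male profile times a ratio (~0.76)
estimated from the two same-year male/female anchor pairs.  Outside
1980–2012 the nearest anchor is held.  There is no inter-person intensity
heterogeneity — the published inputs provide none — so pack-years are a
deterministic function of initiation and quit ages.  Under these defaults
no smoker reaches 20 cigarettes/day, so the heavy other-cause-mortality
band is empty in the default conditions (the machinery exists and is
tested with synthetic intensities).

## Natural history

A parametric surrogate with the minimal mechanism supporting the outcomes:

* **Onset hazard.** `h(a) = level_sex · Weibull(a; shape 5, scale 40, onset
  from age 30) · [1 + β_sex · PY(a)^η · d(a)]` with `d = exp(−δ·years
  since quit)` for former smokers, 1 for current, and never-smokers exactly
  at baseline.  Defaults: η = 1, δ = 0.05/year, β_male = 0.5, β_female =
  0.3 per pack-year.  The sex-specific β encodes that a large share of
  female lung-cancer deaths in China occur in never-smokers (indoor air
  pollution and secondhand smoke raise the female baseline, equivalently
  lowering the *relative* smoking effect); with these defaults the
  simulated never-smoker share of deaths comes out near the published
  ~23%, which is not itself calibrated.  `level_sex` is set by calibration.
* **Detection channels.** A preclinical sojourn (exponential, mean 4 years)
  separates onset from symptomatic detection.  Incidental detection during
  unrelated imaging fires annually at rate 0.01 while preclinical; it moves
  the diagnosis age (ending screening eligibility) but never the death age
  — the model credits no survival change to earlier diagnosis per se.
* **Stage and survival.** Stage at symptomatic detection is categorical
  (I–IV: 0.10/0.10/0.25/0.55).  A stage-specific cure fraction
  (0.55/0.30/0.10/0.02) decides cure; non-cured cases die an exponential
  time after detection (means 5/3/1.5/0.7 years).  Lung-cancer deaths after
  age 84 are censored by the exit age.
* **Screening benefit = stage shift only.**  Screen detection redraws stage
  from `(1 − w) · clinical + w · early` with early = 0.70/0.17/0.09/0.04
  and `w` ("stage-shift strength") set by calibration.  The cure decision
  reuses the person's clinical-pathway uniform and takes the better of the
  two cure fractions, so screen detection can only match or improve the
  clinical outcome, and if it does not cure, the death age stays anchored
  at the clinical pathway's death age.  This construction makes "screening
  never causes an earlier lung-cancer death" and "deaths prevented ≥ 0
  under common random numbers" exact structural properties rather than
  statistical tendencies, and excludes lead-time bias by design.
* **Other-cause mortality.** Gompertz–Makeham annual probabilities per sex
  (Makeham 1.2e-3/0.8e-3, Gompertz coefficient 3.2e-5/2.0e-5, rate 0.092)
  with band multipliers 1.0 (never) / 1.5 (light) / 2.0 (heavy ≥ 20
  cigarettes/day mean).  These are synthetic life tables, not fitted to any
  published table; they provide a plausible competing risk with life
  expectancy at 15 of ~60 (male) / ~63 (female) further years.

The sojourn distribution, stage distributions, cure fractions and survival
means are this package's declared choices, not inferred from any source;
the calibration anchors (below) are what tie the surrogate to published
quantities, and results are correspondingly insensitive to, e.g., the CT
sensitivity scalar (default 0.85/visit) because the stage-shift strength is
recalibrated against the same anchor.

## Screening module

Eligibility at (age, year): age within the policy window, accumulated
pack-years ≥ threshold, and — for former smokers — years since quit ≤ the
allowed window; all bounds inclusive (the published rule wording alternates
between "no more than" and "fewer than" 15 years; the inclusive reading is
adopted).  Never-smokers are never eligible.  CMS = (55–77, 30 pack-years,
15 years); CNG = (50–74, 20 pack-years, 5 years); both annual, 2016–2050,
100% adherence in the base case.  Because pack-years are nondecreasing and
freeze at quit, each person's eligible ages form one contiguous interval,
which the vectorized engine exploits.

Adherence is per-person (an always/never attender drawn once at first
eligibility), the conservative reading of a population adherence sweep; it
makes expected screens exactly linear in the adherence fraction.  Diagnosed
people exit screening permanently.

## Common random numbers

Every stream is seeded by (seed, sex, birth year, stream index) with
fixed-size draws, so scenarios share identical people, histories, tumors
and other-cause deaths, and even the screening draws (adherence uniform,
per-visit sensitivity, screen-stage uniform) are policy-independent.
Consequences used by the tests: never-smoker tallies are bit-identical
across scenarios; setting CT sensitivity to 0 reproduces the baseline
bit-for-bit; policy contrasts are free of between-scenario sampling noise.

## Calibration

Three stages; later stages never touch earlier fits.

1. **Initiation curves vs prevalence anchors (deterministic).**  The
   objective is the closed-form expected prevalence over ages 35–74 (the
   survey's sampling frame) including differential other-cause survival of
   ever-smokers — no Monte-Carlo noise.  Nelder–Mead from a seeded
   Latin-hypercube of restarts; the internal fitting loss is
   tolerance-normalized and high-power (≈ minimax), since the contract is
   per-anchor tolerance, while the reported diagnostic loss is the weighted
   squared relative error.  Typical result: all 12 anchors within ~3%
   (tolerance 5%).
2. **Baseline hazard levels vs 2012 deaths (exact profile scan).**  Under
   common random numbers each person's death year is a piecewise-constant
   function of `level_sex`: onset is the first age where `level ×
   (cumulative unit hazard)` exceeds the person's Exp(1) draw, and the
   sojourn + survival delay is level-independent.  One simulation pass per
   sex therefore yields, per person, the interval of levels that place
   their death in 2012, and scaled deaths-in-2012 as a function of the
   level is computed exactly and inverted.  The count is not globally
   monotone (at absurd levels every onset collapses to the earliest hazard
   age), so the smallest level reaching the target — the physical branch —
   is selected.  Achieved error is one scale-weight (~0.05%) rather than
   the 2% tolerance.
3. **Stage-shift strength vs the trial anchor (bisection).**  The target is
   the 19.7% mortality reduction among people ever meeting CMS criteria in
   the 1960 birth cohort (100,000 per sex), simulated with and without
   screening under common random numbers.  The subgroup reduction is
   monotone nondecreasing in `w` by the coupling construction, so bisection
   on [0, 1] converges; with the default stage/cure settings the anchor is
   met at `w ≈ 0.5–0.6`, comfortably interior.  An anchor above the
   full-shift reduction is reported as infeasible rather than forced.

## Problem sizes and reproducibility

Defaults chosen for desk-scale work: 50,000 people per cohort for the
mortality stage and its verification, 100,000 per sex for the 1960-cohort
anchor, 20,000 per cohort for the three-scenario comparison (a full
comparison over all 145 cohorts runs in well under a minute), and smaller
sizes in sweeps.  All results are pure functions of (parameters, seed);
rerunning any driver with the same seed reproduces output files byte for
byte.  Scenario tallies are kept resolved by (cohort, year, sex, smoking
status), so scaling commutes with aggregation.

## What the synthetic stand-ins do and do not show

The population projection (logistic rise-then-decline cohort sizes, ~51/49
sex split, aged with the synthetic life tables, ~0.65 billion adults) and
the Gompertz–Makeham life tables are structural stand-ins for external data
that is not redistributed here.  Calibrated quantities (2012 deaths by sex,
prevalence anchors, the subgroup anchor) are reproduced on top of the
stand-ins by construction of the calibration, and policy *contrasts* — CMS
male reduction above CNG's, CNG female reduction above CMS's, CNG requiring
~1.5× the screens and more eligible people every year, more life-years per
death prevented under CNG — emerge from the eligibility rules and the
smoking model and match the published direction.  Absolute 2016–2050 counts
(total deaths, total screens, deaths prevented) depend on the real census
projection and are **not** reproduced; the published versions of those
numbers are used only as inputs to arithmetic-consistency checks of the
outcome operations.  Passing tests therefore demonstrate internal
consistency and faithful mechanism, not a re-estimate of China's absolute
screening burden.

One knock-on effect deserves emphasis: under the printed prevalence and
cessation inputs nearly all simulated males are ever-smokers, and without
intensity heterogeneity most male lung-cancer deaths occur among people who
eventually meet CMS criteria, so the model's overall mortality reductions
(~11–15%) sit above the published ones (~5–7%).  Relative sensitivities are
comparable, but anything expressed in absolute percentage points of
reduction — notably the cessation-doubling sweep, which moves the reduction
by about one point here — scales up with that level.

## Known limitations

* No urban/rural, education or province stratification; no secondhand-smoke
  or air-pollution exposure variables (the female baseline hazard absorbs
  them in aggregate).
* No benign-nodule false positives, no observed-vs-true stage discordance,
  no treatment detail, no overdiagnosis or radiation-risk tallies, no
  costs, no discounting.
* One-way cessation without relapse; deterministic intensity given
  (sex, age, year).
* Annual resolution censors within-year ordering; ties between same-year
  competing events are resolved by fixed rules (other-cause death at an
  integer age precludes that year's screen).
* The initiation-curve knot levels are identified only in moving average;
  alternative level patterns fitting the same anchors would shift
  cohort-resolved outputs somewhat.
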