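# lcpm — lung cancer screening policy microsimulation for China

More than half of Chinese men smoke, and lung-cancer deaths in China will
number in the millions over the coming decades.  Two CT-screening
eligibility rules compete for a national program: the U.S. CMS criteria
(ages 55–77, ≥ 30 pack-years, ≤ 15 years since quitting) and the Chinese
national guideline ("CNG": ages 50–74, ≥ 20 pack-years, ≤ 5 years since
quitting).  `lcpm` is a person-level microsimulation for comparing such
policies on lung-cancer mortality reduction, life-years saved and screening
burden over 2016–2050.  It is aimed at modelers and epidemiologists who
need a transparent, fully seeded, desk-scale policy model rather than a
black box.

## Model in brief

For each member of every birth cohort (entering at age 15, 1891–2035):

* a smoking life-course — initiation age from a cohort-specific cumulative
  logistic F(a) = L(c)·σ(k(a−a₀)), one-way annual cessation at the
  published rates (2%/yr from age 30 for men, 3% above 65; 2% from 35 for
  women), deterministic cigarettes/day by sex, age and calendar year; pack-
  years PY(a) accrue as cpd/20 per year smoked;
* lung-cancer onset with annual hazard
  h(a) = γ_sex·b₀(a)·[1 + β_sex·PY(a)·e^(−δq)], b₀ Weibull in age, q years
  since quitting; a preclinical sojourn to symptomatic detection; stage at
  detection; stage-specific cure fraction and survival;
* screening: annual CT while eligible; screen detection redraws stage from
  an earlier-stage distribution (strength w), and the coupled cure decision
  can only match or improve the clinical outcome — no lead-time credit;
* competing other-cause death from sex- and smoking-band-stratified life
  tables.

Free parameters are set by staged calibration to published targets: the
initiation curves to 12 smoking-prevalence anchors (CHNS 1991–2006), the
baseline hazard levels to the 2012 lung-cancer death counts (422,000 men /
175,000 women, GLOBOCAN), and the stage-shift strength to the 19.7%
mortality reduction among screened-eligible members of the 1960 birth
cohort (the NLST-anchored validation quantity).  External inputs the model
needs but cannot redistribute (census population projection, GBD life
tables) are generated as declared synthetic stand-ins, so absolute
population counts are in synthetic units while calibrated targets and
policy contrasts are meaningful.  See `docs/methods.md` for the full
account.

## Worked example

```sh
python analysis/01_calibrate.py --seed 1 --out results
python analysis/02_compare_policies.py --seed 1 --out results
python analysis/03_sensitivity.py --seed 1 --out results
```

The calibration step prints (seed 1, 50,000 people per cohort for the
mortality stage):

```
initiation: 12 target(s), worst |relative error| 0.0256, all within tolerance: True
mortality: 2 target(s), worst |relative error| 0.0000, all within tolerance: True
screening_benefit: 1 target(s), worst |relative error| 0.0009, all within tolerance: True
```

meaning every prevalence anchor is matched within 2.6% (tolerance 5%), the
2012 death counts essentially exactly (tolerance 2%), and the
screened-subgroup mortality reduction lands within 0.1% of the 19.7%
anchor.  The comparison step then prints (20,000 per cohort):

```
cms: prevented 2.94e+06 deaths, reduction male 15.07% / female 1.36%, 6.4 life-years per death, 1.75e+09 screens
cng: prevented 2.72e+06 deaths, reduction male 13.54% / female 2.33%, 7.9 life-years per death, 2.63e+09 screens
screens ratio cng/cms: 1.500
```

Read these as *contrasts*, in synthetic-population units: the CMS rule
achieves the higher male mortality reduction (it captures older, heavier
smokers), the Chinese guideline the higher female reduction (it admits the
lighter smoking histories typical of Chinese women) and more life-years
per death prevented (it screens younger people), at the cost of ~1.5× the
screens — the direction of every published comparison.  Absolute counts
depend on the real census projection and are deliberately not reproduced.

The same functionality is available as a console script
(`lcpm calibrate|simulate|compare|sensitivity`, see `lcpm --help`); every
output CSV records the seed and reruns are byte-identical.

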