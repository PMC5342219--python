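"""Model inputs: smoking rates, natural-history settings, screening policies.

Every published input of the China lung-cancer policy microsimulation lives
here as a typed, validated parameter set with JSON round-tripping:

* cross-sectional smoking prevalence anchors (CHNS, 1991-2006) used as
  calibration targets,
* annual cessation probabilities by sex and age band,
* cigarettes smoked per day by age and calendar year,
* the 2012 lung-cancer death counts (GLOBOCAN) used as calibration targets,
* lung-cancer histology shares by sex and diagnosis period,
* the two CT-screening eligibility rules that the model compares (U.S. CMS
  and the Chinese national guideline, "CNG"),
* the parametric natural-history surrogate (baseline hazard, smoking excess
  risk, sojourn, stage, cure/survival) whose free parameters are set by
  calibration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SEXES",
    "STAGES",
    "HISTOLOGIES",
    "PERIODS",
    "SMOKING_STATUSES",
    "ParameterError",
    "InitiationCurve",
    "SmokingParameters",
    "NaturalHistoryParameters",
    "OtherCauseParameters",
    "PopulationParameters",
    "HistologyTable",
    "ScreeningPolicy",
    "CalibrationTarget",
    "ParameterBundle",
    "default_parameters",
    "default_targets",
    "cms_policy",
    "cng_policy",
    "cigarettes_per_day",
    "histology_distribution",
    "load_parameters",
    "save_parameters",
]

SEXES = ("male", "female")
STAGES = ("I", "II", "III", "IV")
HISTOLOGIES = ("adenocarcinoma", "squamous", "small_cell", "large_other")
PERIODS = ("1991-1995", "1996-2000", "2001-2005")
SMOKING_STATUSES = ("never", "current", "former")

#: modelled age range: people enter at 15 and exit (alive) at 85
AGE_MIN = 15
AGE_MAX = 84

#: reporting window for all population tallies
YEAR_MIN = 1975
YEAR_MAX = 2050


class ParameterError(ValueError):
    """A parameter file or bundle failed validation."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise ParameterError(f"unknown sex label {sex!r}; expected one of {SEXES}") from None


# ---------------------------------------------------------------------------
# smoking
# ---------------------------------------------------------------------------


@dataclass
class InitiationCurve:
    """Cumulative smoking-initiation curve for one sex.

    The probability of having initiated by (integer) age ``a`` for a person
    born in year ``c`` is a logistic in age,

        F(a; c) = L(c) / (1 + exp(-k (a - a0))),

    where the level ``L(c)`` (the eventual ever-smoker fraction) is piecewise
    linear across birth-cohort knots and held flat outside them.  ``a0`` and
    ``k`` are shared across cohorts within a sex.  The three level knots, the
    midpoint and the slope are the free parameters set by calibration to the
    prevalence targets.
    """

    cohort_knots: list[int] = field(default_factory=lambda: [1920, 1945, 1970])
    levels: list[float] = field(default_factory=lambda: [0.5, 0.5, 0.5])
    midpoint: float = 20.0
    slope: float = 0.5

    def validate(self) -> None:
        _check(len(self.cohort_knots) == len(self.levels),
               "initiation_params: cohort_knots and levels must have equal length")
        _check(all(0.0 <= v <= 1.0 for v in self.levels),
               "initiation_params: levels must lie in [0, 1]")
        _check(self.slope > 0, "initiation_params: slope must be positive")

    def level(self, birth_year: float | np.ndarray) -> np.ndarray:
        return np.interp(birth_year, self.cohort_knots, self.levels)

    def cdf(self, ages: np.ndarray, birth_year: float) -> np.ndarray:
        """P(initiated by age a) on an age grid, for one birth cohort."""
        lvl = float(self.level(birth_year))
        return lvl / (1.0 + np.exp(-self.slope * (np.asarray(ages, float) - self.midpoint)))


@dataclass
class SmokingParameters:
    """Initiation, cessation and intensity inputs for the smoking module."""

    #: (age_lo, age_hi, annual quit probability) bands per sex; cessation is
    #: tracked from age 30 for males and 35 for females, zero below.
    cessation_schedule: dict[str, list[list[float]]] = field(default_factory=lambda: {
        "male": [[30, 65, 0.02], [66, 200, 0.03]],
        "female": [[35, 200, 0.02]],
    })
    #: male cigarettes/day age anchors observed in 2006
    cpd_age_profile: list[list[float]] = field(default_factory=lambda: [
        [37, 16.56], [46, 17.44], [55, 15.76], [66, 13.2], [74, 12.2],
    ])
    #: population cigarettes/day calendar anchors (both sexes pooled)
    cpd_year_trend: list[list[float]] = field(default_factory=lambda: [
        [1980, 15.5], [1996, 18.2], [2006, 21.8], [2012, 22.3],
    ])
    #: reference year at which the age profile was observed
    cpd_reference_year: int = 2006
    #: same-year male and female cigarettes/day pairs used to set the female
    #: intensity relative to males (year -> [female, male])
    cpd_sex_anchor_pairs: dict[str, list[float]] = field(default_factory=lambda: {
        "1998": [12.3, 15.8], "2003": [15.8, 21.3],
    })
    initiation_params: dict[str, InitiationCurve] = field(default_factory=lambda: {
        "male": InitiationCurve(cohort_knots=[1920, 1938, 1948, 1956, 1964, 1972],
                                levels=[0.9, 0.9, 0.88, 0.85, 0.82, 0.8],
                                midpoint=21.0, slope=0.5),
        "female": InitiationCurve(cohort_knots=[1918, 1928, 1936, 1944, 1952, 1962, 1972],
                                  levels=[0.10, 0.10, 0.08, 0.06, 0.05, 0.04, 0.03],
                                  midpoint=20.0, slope=0.5),
    })
    #: multiplier applied to cessation probabilities from a given calendar
    #: year onward (sensitivity-analysis lever; 1.0 = base case)
    cessation_multiplier: float = 1.0
    cessation_multiplier_start_year: int = 2016

    def validate(self) -> None:
        for sex in SEXES:
            _check(sex in self.cessation_schedule,
                   f"cessation_schedule: missing entry for {sex!r}")
            for lo, hi, p in self.cessation_schedule[sex]:
                _check(0.0 <= p <= 1.0,
                       f"cessation_schedule[{sex}]: probability {p} outside [0, 1]")
                _check(lo <= hi, f"cessation_schedule[{sex}]: empty age band ({lo}, {hi})")
            _check(sex in self.initiation_params,
                   f"initiation_params: missing entry for {sex!r}")
            curve = self.initiation_params[sex]
            if not isinstance(curve, InitiationCurve):  # loaded from JSON
                curve = InitiationCurve(**curve)
                self.initiation_params[sex] = curve
            curve.validate()
        _check(all(v >= 0 for _, v in self.cpd_age_profile),
               "cpd_age_profile: cigarettes/day must be nonnegative")
        _check(all(v >= 0 for _, v in self.cpd_year_trend),
               "cpd_year_trend: cigarettes/day must be nonnegative")
        _check(self.cessation_multiplier >= 0, "cessation_multiplier must be >= 0")

    # -- cessation ---------------------------------------------------------

    def cessation_start_age(self, sex: str) -> int:
        return int(min(lo for lo, _, _ in self.cessation_schedule[sex]))

    def cessation(self, sex: str, age: float, year: int | None = None) -> float:
        """Annual quit probability at a given age (and calendar year)."""
        sex_index(sex)
        rate = 0.0
        for lo, hi, p in self.cessation_schedule[sex]:
            if lo <= age <= hi:
                rate = p
                break
        if (year is not None and self.cessation_multiplier != 1.0
                and year >= self.cessation_multiplier_start_year):
            rate = min(1.0, rate * self.cessation_multiplier)
        return rate

    def cessation_curve(self, sex: str, birth_year: int) -> np.ndarray:
        """Annual quit probability on the age grid 15..84 for one cohort."""
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        out = np.zeros(ages.shape)
        for i, a in enumerate(ages):
            out[i] = self.cessation(sex, int(a), birth_year + int(a))
        return out

    # -- intensity ---------------------------------------------------------

    @property
    def female_intensity_ratio(self) -> float:
        pairs = [v for v in self.cpd_sex_anchor_pairs.values()]
        return float(np.mean([f / m for f, m in pairs]))


def cigarettes_per_day(sex: str, age, year, params: SmokingParameters | None = None):
    """Cigarettes smoked per day by a current smoker of the given sex/age/year.

    The male age profile (anchored in 2006) is carried across calendar time by
    the pooled year trend, normalized at the reference year; female intensity
    is the male profile scaled by the ratio estimated from same-year
    male/female anchors.  Between anchors values interpolate linearly; outside
    the anchored range the nearest anchor is held (intensity data cover
    1980-2012 only).
    """
    params = params or _DEFAULT_SMOKING
    idx = sex_index(sex)
    age = np.asarray(age, dtype=float)
    year = np.asarray(year, dtype=float)
    prof_ages, prof_vals = zip(*params.cpd_age_profile)
    trend_years, trend_vals = zip(*params.cpd_year_trend)
    profile = np.interp(age, prof_ages, prof_vals)
    trend = np.interp(year, trend_years, trend_vals)
    ref = np.interp(params.cpd_reference_year, trend_years, trend_vals)
    out = profile * trend / ref
    if idx == 1:
        out = out * params.female_intensity_ratio
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# natural history
# ---------------------------------------------------------------------------


@dataclass
class NaturalHistoryParameters:
    """Parametric surrogate for lung-cancer onset, detection and survival.

    Annual onset hazard at age ``a`` for a person with pack-years ``PY(a)``:

        h(a) = level_sex * b0(a) * [1 + beta_sex * PY(a)**eta * decay(q)]

    with ``b0`` a Weibull hazard in age, ``decay(q) = exp(-delta q)`` for a
    former smoker ``q`` years after quitting and 1 for current smokers.  A
    preclinical sojourn (exponential) separates onset from symptomatic
    ("clinical") detection; stage at detection is drawn from a categorical
    distribution, a stage-specific cure fraction decides survival, and
    non-cured cases die an exponential time after detection.  Screen detection
    redraws stage from a distribution shifted toward early stage but never
    moves a death earlier than the clinical pathway.
    """

    baseline_age_min: float = 30.0
    baseline_shape: float = 5.0
    baseline_scale: float = 40.0
    #: per-sex multiplier on the Weibull hazard; set by mortality calibration
    baseline_level: dict[str, float] = field(default_factory=lambda: {
        "male": 2.0e-3, "female": 2.0e-3,
    })
    #: per-sex excess-risk coefficient per pack-year
    smoking_beta: dict[str, float] = field(default_factory=lambda: {
        "male": 0.5, "female": 0.3,
    })
    smoking_eta: float = 1.0
    quit_decay_rate: float = 0.05
    sojourn_mean_years: float = 4.0
    incidental_detection_rate: float = 0.01
    stage_distribution_clinical: list[float] = field(
        default_factory=lambda: [0.10, 0.10, 0.25, 0.55])
    #: fully stage-shifted distribution at screen detection; the effective
    #: screen distribution interpolates toward it with `stage_shift`
    stage_distribution_early: list[float] = field(
        default_factory=lambda: [0.70, 0.17, 0.09, 0.04])
    #: stage-shift strength in [0, 1]; set by the screening-benefit calibration
    stage_shift: float = 0.7
    cure_fraction: list[float] = field(default_factory=lambda: [0.55, 0.30, 0.10, 0.02])
    survival_mean_years: list[float] = field(default_factory=lambda: [5.0, 3.0, 1.5, 0.7])
    ct_sensitivity: float = 0.85

    def validate(self) -> None:
        for name in ("baseline_shape", "baseline_scale", "smoking_eta",
                     "sojourn_mean_years"):
            _check(getattr(self, name) > 0, f"natural_history.{name} must be positive")
        _check(self.quit_decay_rate >= 0, "natural_history.quit_decay_rate must be >= 0")
        for sex in SEXES:
            _check(self.baseline_level.get(sex, -1) >= 0,
                   f"natural_history.baseline_level[{sex}] must be >= 0")
            _check(self.smoking_beta.get(sex, -1) >= 0,
                   f"natural_history.smoking_beta[{sex}] must be >= 0")
        for name in ("stage_distribution_clinical", "stage_distribution_early"):
            dist = getattr(self, name)
            _check(len(dist) == 4 and abs(sum(dist) - 1.0) < 1e-6 and min(dist) >= 0,
                   f"natural_history.{name} must be a probability vector over 4 stages")
        _check(0.0 <= self.stage_shift <= 1.0, "natural_history.stage_shift must be in [0, 1]")
        _check(all(0.0 <= c <= 1.0 for c in self.cure_fraction),
               "natural_history.cure_fraction entries must lie in [0, 1]")
        _check(all(m > 0 for m in self.survival_mean_years),
               "natural_history.survival_mean_years entries must be positive")
        _check(0.0 <= self.incidental_detection_rate <= 1.0,
               "natural_history.incidental_detection_rate must be in [0, 1]")
        _check(0.0 <= self.ct_sensitivity <= 1.0,
               "natural_history.ct_sensitivity must be in [0, 1]")

    def stage_distribution_screen(self) -> np.ndarray:
        clin = np.asarray(self.stage_distribution_clinical)
        early = np.asarray(self.stage_distribution_early)
        return (1.0 - self.stage_shift) * clin + self.stage_shift * early

    def baseline_hazard(self, sex: str, ages) -> np.ndarray:
        """Never-smoker annual onset hazard b(a) = level * Weibull(a)."""
        sex_index(sex)
        a = np.maximum(np.asarray(ages, float) - self.baseline_age_min, 0.0)
        k, lam = self.baseline_shape, self.baseline_scale
        return self.baseline_level[sex] * (k / lam) * (a / lam) ** (k - 1.0)


@dataclass
class OtherCauseParameters:
    """Gompertz-Makeham life-table generator settings.

    Annual other-cause death probability q(a) = makeham + coef * exp(rate*a),
    multiplied by a smoking-intensity band factor (never / light / heavy) and
    capped at 1.  Smokers with mean intensity at or above
    ``heavy_cpd_threshold`` cigarettes/day use the heavy band.
    """

    makeham: dict[str, float] = field(default_factory=lambda: {
        "male": 1.2e-3, "female": 0.8e-3,
    })
    gompertz_coef: dict[str, float] = field(default_factory=lambda: {
        "male": 3.2e-5, "female": 2.0e-5,
    })
    gompertz_rate: float = 0.092
    band_multipliers: list[float] = field(default_factory=lambda: [1.0, 1.5, 2.0])
    heavy_cpd_threshold: float = 20.0

    def validate(self) -> None:
        for sex in SEXES:
            _check(self.makeham.get(sex, -1) >= 0, f"other_cause.makeham[{sex}] must be >= 0")
            _check(self.gompertz_coef.get(sex, -1) >= 0,
                   f"other_cause.gompertz_coef[{sex}] must be >= 0")
        _check(self.gompertz_rate > 0, "other_cause.gompertz_rate must be positive")
        _check(len(self.band_multipliers) == 3
               and all(m >= 1 or i == 0 for i, m in enumerate(self.band_multipliers)),
               "other_cause.band_multipliers must give 3 bands")
        ms = self.band_multipliers
        _check(ms[0] <= ms[1] <= ms[2],
               "other_cause.band_multipliers must be nondecreasing (never <= light <= heavy)")


@dataclass
class PopulationParameters:
    """Synthetic stand-in for the census population projection.

    Cohort sizes at age 15 follow a logistic rise then decline in birth year;
    the projection does not attempt to match the real census, so absolute
    population counts are reported in synthetic-population units.
    """

    base_cohort_size: float = 16.0e6
    rise_midpoint: float = 1925.0
    rise_scale: float = 12.0
    decline_midpoint: float = 2006.0
    decline_scale: float = 12.0
    male_fraction: float = 0.515

    def validate(self) -> None:
        _check(self.base_cohort_size > 0, "population.base_cohort_size must be positive")
        _check(0.0 < self.male_fraction < 1.0, "population.male_fraction must be in (0, 1)")
        _check(self.rise_scale > 0 and self.decline_scale > 0,
               "population growth scales must be positive")

    def cohort_size_at_entry(self, birth_year) -> np.ndarray:
        c = np.asarray(birth_year, dtype=float)
        rise = 1.0 / (1.0 + np.exp(-(c - self.rise_midpoint) / self.rise_scale))
        decline = 1.0 / (1.0 + np.exp(-(c - self.decline_midpoint) / self.decline_scale))
        return self.base_cohort_size * rise * (1.0 - decline)


# ---------------------------------------------------------------------------
# histology
# ---------------------------------------------------------------------------

_DEFAULT_HISTOLOGY = {
    "male|1991-1995": [30, 54, 13, 3],
    "male|1996-2000": [31, 52, 13, 4],
    "male|2001-2005": [33, 52, 10, 5],
    "female|1991-1995": [51, 32, 15, 2],
    "female|1996-2000": [55, 32, 10, 3],
    "female|2001-2005": [54, 34, 8, 4],
}


@dataclass
class HistologyTable:
    """Histology shares (percent) by sex and diagnosis period."""

    shares: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_HISTOLOGY.items()})

    def validate(self) -> None:
        for sex in SEXES:
            for period in PERIODS:
                key = f"{sex}|{period}"
                _check(key in self.shares, f"histology.shares: missing row {key!r}")
                row = self.shares[key]
                _check(len(row) == len(HISTOLOGIES),
                       f"histology.shares[{key}]: expected {len(HISTOLOGIES)} entries")
                _check(abs(sum(row) - 100.0) <= 2.0,
                       f"histology.shares[{key}]: percentages sum to {sum(row)}, "
                       "outside 100 +/- 2")

    @staticmethod
    def period_for_year(year: int) -> str:
        if year <= 1995:
            return PERIODS[0]
        if year <= 2000:
            return PERIODS[1]
        return PERIODS[2]

    def distribution(self, sex: str, period) -> np.ndarray:
        sex_index(sex)
        if isinstance(period, (int, np.integer)):
            period = self.period_for_year(int(period))
        if period not in PERIODS:
            raise ParameterError(f"unknown histology period {period!r}")
        row = np.asarray(self.shares[f"{sex}|{period}"], dtype=float)
        return row / row.sum()


def histology_distribution(sex: str, period, table: HistologyTable | None = None) -> np.ndarray:
    """Probability vector over the four histological subtypes."""
    return (table or _DEFAULT_HISTOLOGY_TABLE).distribution(sex, period)


# ---------------------------------------------------------------------------
# screening policies
# ---------------------------------------------------------------------------


@dataclass
class ScreeningPolicy:
    """Declarative annual-CT screening eligibility rule.

    Eligibility at (age, year): ``age_min <= age <= age_max``, accumulated
    pack-years at least ``min_pack_years`` and — for former smokers — at most
    ``max_years_since_quit`` years since quitting (all bounds inclusive).
    Never-smokers are never eligible.
    """

    name: str
    age_min: int
    age_max: int
    min_pack_years: float
    max_years_since_quit: float
    interval: int = 1
    start_year: int = 2016
    end_year: int = 2050
    adherence: float = 1.0

    def validate(self) -> None:
        _check(self.age_min <= self.age_max,
               f"policy {self.name!r}: age_min must not exceed age_max")
        _check(self.min_pack_years >= 0, f"policy {self.name!r}: min_pack_years must be >= 0")
        _check(self.max_years_since_quit >= 0,
               f"policy {self.name!r}: max_years_since_quit must be >= 0")
        _check(self.interval >= 1, f"policy {self.name!r}: interval must be >= 1")
        _check(self.start_year <= self.end_year,
               f"policy {self.name!r}: start_year must not exceed end_year")
        _check(0.0 <= self.adherence <= 1.0,
               f"policy {self.name!r}: adherence must lie in [0, 1]")


def cms_policy(**overrides) -> ScreeningPolicy:
    """U.S. CMS criteria: ages 55-77, >=30 pack-years, <=15 years since quit."""
    kw = dict(name="cms", age_min=55, age_max=77, min_pack_years=30.0,
              max_years_since_quit=15.0)
    kw.update(overrides)
    return ScreeningPolicy(**kw)


def cng_policy(**overrides) -> ScreeningPolicy:
    """Chinese national guideline: ages 50-74, >=20 pack-years, <=5 years since quit."""
    kw = dict(name="cng", age_min=50, age_max=74, min_pack_years=20.0,
              max_years_since_quit=5.0)
    kw.update(overrides)
    return ScreeningPolicy(**kw)


# ---------------------------------------------------------------------------
# calibration targets
# ---------------------------------------------------------------------------

_TARGET_KINDS = ("prevalence", "mortality_count", "histology_share",
                 "screening_effectiveness")


@dataclass
class CalibrationTarget:
    """A named published statistic that calibration must reproduce."""

    name: str
    kind: str
    sex: str | None
    year: int | None
    value: float
    weight: float = 1.0
    rel_tolerance: float = 0.05
    period: str | None = None

    def validate(self) -> None:
        _check(self.kind in _TARGET_KINDS,
               f"target {self.name!r}: unknown kind {self.kind!r}")
        _check(self.value >= 0, f"target {self.name!r}: value must be >= 0")
        _check(self.weight > 0, f"target {self.name!r}: weight must be positive")


_PREVALENCE_TARGETS = {
    "male": {1991: 0.66, 1993: 0.65, 1997: 0.62, 2000: 0.58, 2004: 0.59, 2006: 0.57},
    "female": {1991: 0.062, 1993: 0.061, 1997: 0.055, 2000: 0.053, 2004: 0.041, 2006: 0.035},
}

_MORTALITY_TARGETS = {"male": 422_000.0, "female": 175_000.0}

#: mortality reduction within the screened-eligible subgroup of the 1960 birth
#: cohort, anchoring screening effectiveness to the NLST finding
NLST_ANCHOR = 0.197


def default_targets() -> list[CalibrationTarget]:
    targets = []
    for sex in SEXES:
        for year, value in _PREVALENCE_TARGETS[sex].items():
            targets.append(CalibrationTarget(
                name=f"prevalence_{sex}_{year}", kind="prevalence", sex=sex,
                year=year, value=value, rel_tolerance=0.05))
        targets.append(CalibrationTarget(
            name=f"lc_deaths_2012_{sex}", kind="mortality_count", sex=sex,
            year=2012, value=_MORTALITY_TARGETS[sex], rel_tolerance=0.02))
    targets.append(CalibrationTarget(
        name="nlst_subgroup_reduction_1960", kind="screening_effectiveness",
        sex=None, year=1960, value=NLST_ANCHOR, rel_tolerance=0.076))
    return targets


# ---------------------------------------------------------------------------
# bundle + IO
# ---------------------------------------------------------------------------


@dataclass
class ParameterBundle:
    """Every input the simulation needs, in one validated object."""

    smoking: SmokingParameters = field(default_factory=SmokingParameters)
    natural_history: NaturalHistoryParameters = field(default_factory=NaturalHistoryParameters)
    other_cause: OtherCauseParameters = field(default_factory=OtherCauseParameters)
    population: PopulationParameters = field(default_factory=PopulationParameters)
    histology: HistologyTable = field(default_factory=HistologyTable)
    policies: dict[str, ScreeningPolicy] = field(
        default_factory=lambda: {"cms": cms_policy(), "cng": cng_policy()})
    targets: list[CalibrationTarget] = field(default_factory=default_targets)

    def validate(self) -> "ParameterBundle":
        self.smoking.validate()
        self.natural_history.validate()
        self.other_cause.validate()
        self.population.validate()
        self.histology.validate()
        for policy in self.policies.values():
            policy.validate()
        for target in self.targets:
            target.validate()
        return self

    def replace(self, **sections) -> "ParameterBundle":
        return dataclasses.replace(self, **sections)


def default_parameters() -> ParameterBundle:
    """The full default bundle, populated with every published input."""
    return ParameterBundle().validate()


_SECTION_TYPES = {
    "smoking": SmokingParameters,
    "natural_history": NaturalHistoryParameters,
    "other_cause": OtherCauseParameters,
    "population": PopulationParameters,
    "histology": HistologyTable,
}

_REQUIRED_SMOKING_FIELDS = ("cessation_schedule", "initiation_params")


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_parameters(bundle: ParameterBundle, path) -> None:
    """Write a bundle as a sectioned JSON parameter file."""
    payload = {
        "smoking": _to_jsonable(bundle.smoking),
        "natural_history": _to_jsonable(bundle.natural_history),
        "other_cause": _to_jsonable(bundle.other_cause),
        "population": _to_jsonable(bundle.population),
        "histology": _to_jsonable(bundle.histology),
        "policies": {k: _to_jsonable(v) for k, v in bundle.policies.items()},
        "targets": [_to_jsonable(t) for t in bundle.targets],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _build_section(cls, data: Mapping, section: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ParameterError(f"{section}: unknown field(s) {sorted(unknown)}")
    try:
        obj = cls(**data)
    except TypeError as exc:
        raise ParameterError(f"{section}: {exc}") from None
    return obj


def load_parameters(path) -> ParameterBundle:
    """Load and validate a bundle saved by :func:`save_parameters`.

    Raises :class:`ParameterError` naming the offending section/field on any
    schema violation.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        if section not in payload:
            raise ParameterError(f"parameter file missing section {section!r}")
        data = dict(payload[section])
        if section == "smoking":
            for name in _REQUIRED_SMOKING_FIELDS:
                if name not in data:
                    raise ParameterError(f"smoking section missing {name!r}")
            data["initiation_params"] = {
                sex: InitiationCurve(**curve)
                for sex, curve in data["initiation_params"].items()
            }
        kwargs[section] = _build_section(cls, data, section)
    kwargs["policies"] = {
        name: _build_section(ScreeningPolicy, pol, f"policies[{name}]")
        for name, pol in payload.get("policies", {}).items()
    }
    kwargs["targets"] = [
        _build_section(CalibrationTarget, t, "targets") for t in payload.get("targets", [])
    ]
    return ParameterBundle(**kwargs).validate()


_DEFAULT_SMOKING = SmokingParameters()
_DEFAULT_HISTOLOGY_TABLE = HistologyTable()
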