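"""Synthetic stand-ins for external inputs (population projection, life tables).

The real model drew its population projection and other-cause mortality from
external databases.  This module generates structurally equivalent stand-ins
from declared parameters so the full pipeline builds and tests offline:

* a population projection with smooth cohort sizes (logistic rise then
  decline in birth year), a ~51/49 male/female split at entry, aged forward
  with the synthetic life tables — deliberately NOT matched to any census,
  so absolute population counts are in synthetic-population units;
* Gompertz-Makeham life tables per sex with multiplicative smoking-intensity
  band factors;
* small fully-specified test cohorts and target-perturbation helpers for
  exercising calibration failure paths.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    AGE_MAX,
    AGE_MIN,
    CalibrationTarget,
    OtherCauseParameters,
    ParameterBundle,
    PopulationParameters,
    SEXES,
    YEAR_MAX,
    YEAR_MIN,
    sex_index,
)
from .natural_history import LifeTable
from .smoking import Person, sample_smoking_history

__all__ = [
    "PopulationProjection",
    "generate_population_projection",
    "generate_life_tables",
    "generate_test_cohort",
    "perturb_targets",
]

_AGES = np.arange(AGE_MIN, AGE_MAX + 1)
_YEARS = np.arange(YEAR_MIN, YEAR_MAX + 1)


@dataclass
class PopulationProjection:
    """People by (calendar year 1975-2050, age 15-84, sex)."""

    counts: np.ndarray  # (years, ages, 2)
    years: np.ndarray = field(default_factory=lambda: _YEARS.copy())
    ages: np.ndarray = field(default_factory=lambda: _AGES.copy())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (len(self.years), len(self.ages), len(SEXES))
        if self.counts.shape != expected:
            raise ValueError(f"projection counts must have shape {expected}")
        if (self.counts < 0).any():
            raise ValueError("projection counts must be nonnegative")

    def at(self, year: int, age: int, sex: str) -> float:
        yi = int(year) - YEAR_MIN
        ai = int(age) - AGE_MIN
        if not (0 <= yi < len(self.years) and 0 <= ai < len(self.ages)):
            raise KeyError(f"projection does not cover (year={year}, age={age})")
        return float(self.counts[yi, ai, sex_index(sex)])

    def adult_population(self, year: int, sex: str | None = None) -> float:
        yi = int(year) - YEAR_MIN
        if not 0 <= yi < len(self.years):
            raise KeyError(f"projection does not cover year {year}")
        sel = self.counts[yi]
        if sex is not None:
            sel = sel[:, sex_index(sex)]
        return float(sel.sum())

    def to_csv(self, path) -> None:
        rows = []
        for yi, year in enumerate(self.years):
            for ai, age in enumerate(self.ages):
                for si, sex in enumerate(SEXES):
                    rows.append((int(year), int(age), sex, self.counts[yi, ai, si]))
        pd.DataFrame(rows, columns=["year", "age", "sex", "count"]) \
            .to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationProjection":
        df = pd.read_csv(path)
        counts = np.zeros((len(_YEARS), len(_AGES), len(SEXES)))
        yi = df["year"].to_numpy() - YEAR_MIN
        ai = df["age"].to_numpy() - AGE_MIN
        si = df["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()
        counts[yi, ai, si] = df["count"].to_numpy()
        return cls(counts=counts)


def generate_life_tables(params: OtherCauseParameters | None = None,
                         seed: int | None = None) -> LifeTable:
    """Gompertz-Makeham annual other-cause death probabilities.

    q(sex, age, band) = multiplier[band] * (makeham + coef * exp(rate*age)),
    capped at 1.  Deterministic; ``seed`` is accepted for interface symmetry
    with the other generators and ignored.
    """
    params = params or OtherCauseParameters()
    params.validate()
    q = np.zeros((len(SEXES), 3, len(_AGES)))
    for si, sex in enumerate(SEXES):
        base = params.makeham[sex] + params.gompertz_coef[sex] * np.exp(
            params.gompertz_rate * _AGES)
        for b, mult in enumerate(params.band_multipliers):
            q[si, b] = np.clip(mult * base, 0.0, 1.0)
    return LifeTable(q=q)


def generate_population_projection(base_cohort_size: float | None = None,
                                   growth_params: PopulationParameters | None = None,
                                   seed: int = 0,
                                   life_table: LifeTable | None = None,
                                   ) -> PopulationProjection:
    """Smooth synthetic population projection over 1975-2050, ages 15-84.

    Cohort sizes at age 15 follow the logistic rise-then-decline shape of
    ``growth_params``; each cohort is split by sex at entry and aged forward
    deterministically with the never-smoker column of the life table (a
    population-average approximation).  Pure function of its parameters;
    ``seed`` is part of the interface for symmetry and reserved for future
    stochastic variants.
    """
    params = growth_params or PopulationParameters()
    if base_cohort_size is not None:
        params = PopulationParameters(
            **{**params.__dict__, "base_cohort_size": float(base_cohort_size)})
    params.validate()
    life_table = life_table or generate_life_tables()
    counts = np.zeros((len(_YEARS), len(_AGES), len(SEXES)))
    sex_frac = (params.male_fraction, 1.0 - params.male_fraction)
    for si, sex in enumerate(SEXES):
        # survival from entry age 15 to each age
        surv = np.concatenate([[1.0], np.cumprod(
            1.0 - life_table.q[si, 0, :-1])])
        for by in range(YEAR_MIN - AGE_MAX, YEAR_MAX - AGE_MIN + 1):
            size15 = params.cohort_size_at_entry(by) * sex_frac[si]
            ages = np.arange(max(AGE_MIN, YEAR_MIN - by),
                             min(AGE_MAX, YEAR_MAX - by) + 1)
            if len(ages) == 0:
                continue
            yi = by + ages - YEAR_MIN
            counts[yi, ages - AGE_MIN, si] = size15 * surv[ages - AGE_MIN]
    return PopulationProjection(counts=counts)


def generate_test_cohort(n: int, sex_mix: float = 0.5, seed: int = 0,
                         bundle: ParameterBundle | None = None,
                         birth_year: int = 1960) -> list[Person]:
    """Fully specified people for unit tests (smoking + other-cause death)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= sex_mix <= 1.0:
        raise ValueError("sex_mix must lie in [0, 1]")
    bundle = bundle or ParameterBundle()
    life_table = generate_life_tables(bundle.other_cause)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    people = []
    for i in range(n):
        sex = "male" if rng.random() < sex_mix else "female"
        history = sample_smoking_history(sex, birth_year, bundle.smoking, rng)
        from .natural_history import other_cause_death_age
        oc = other_cause_death_age(sex, history, life_table, rng,
                                   smoking_params=bundle.smoking)
        people.append(Person(id=i, sex=sex, birth_year=birth_year,
                             smoking=history, oc_death_age=oc))
    return people


def perturb_targets(targets: list[CalibrationTarget], rel_noise: float,
                    seed: int = 0) -> list[CalibrationTarget]:
    """Multiply target values by independent (1 + rel_noise * N(0,1)) factors.

    ``rel_noise=0`` returns an identical copy.  Used to exercise the
    calibration failure path (unmeetable tolerances are reported, not fatal).
    """
    if rel_noise < 0:
        raise ValueError("rel_noise must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(98,)))
    out = []
    for t in targets:
        factor = 1.0 + rel_noise * rng.standard_normal()
        out.append(CalibrationTarget(
            name=t.name, kind=t.kind, sex=t.sex, year=t.year,
            value=max(t.value * factor, 0.0), weight=t.weight,
            rel_tolerance=t.rel_tolerance, period=t.period))
    return out
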