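"""Eligibility rules and the annual CT screening process.

Eligibility under a policy at (age, year) requires: age inside the policy
window, accumulated pack-years at or above the threshold, and — for former
smokers — years since quitting at or below the allowed window (all bounds
inclusive; never-smokers are never eligible).  Because pack-years are
nondecreasing and freeze at quit, each person's eligible ages form one
contiguous interval, which the vector kernels exploit.

Adherence is a per-person trait (always / never attender), drawn once at
first eligibility, so expected screen counts scale linearly with the
adherence fraction.  Diagnosed people exit screening permanently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import AGE_MAX, AGE_MIN, ParameterBundle, ScreeningPolicy
from .smoking import (
    NEVER,
    Person,
    SmokingHistory,
    cumulative_cpd,
    pack_years,
    smoking_status,
    years_since_quit,
)

__all__ = [
    "ScreenEvent",
    "is_eligible",
    "eligibility_bounds",
    "run_screening",
    "count_screens",
    "eligible_fraction",
]


@dataclass
class ScreenEvent:
    person_id: int
    year: int
    age: int
    result: str  # "negative" | "detected"


def is_eligible(policy: ScreeningPolicy, person: Person | SmokingHistory,
                age: float, year: int, smoking_params=None) -> bool:
    """Evaluate the eligibility rule for one person at one (age, year)."""
    history = person.smoking if isinstance(person, Person) else person
    if not (policy.start_year <= year <= policy.end_year):
        return False
    if not (policy.age_min <= age <= policy.age_max):
        return False
    status = smoking_status(history, age)
    if status == "never":
        return False
    if pack_years(history, age, smoking_params) < policy.min_pack_years:
        return False
    if status == "former":
        ysq = years_since_quit(history, age)
        if ysq > policy.max_years_since_quit:
            return False
    return True


def eligibility_bounds(policy: ScreeningPolicy, birth_year: int,
                       init: np.ndarray, quit: np.ndarray,
                       C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vector kernel: each person's contiguous eligible age interval [lo, hi].

    Returns integer ages; an empty interval (lo > hi) means never eligible.
    ``C`` is the cohort pack accumulator from
    :func:`lcpm.smoking.cumulative_cpd`.
    """
    init = np.asarray(init)
    quit = np.asarray(quit)
    # first age at which accumulated pack-years reach the threshold
    need = C[np.clip(init - AGE_MIN, 0, len(C) - 1)] + policy.min_pack_years
    reach_idx = np.searchsorted(C, need, side="left")
    a_py = AGE_MIN + reach_idx
    # pack-years freeze at quit: the threshold must be reached by then
    attained = C[np.clip(np.minimum(quit, NEVER) - AGE_MIN, 0, len(C) - 1)] \
        - C[np.clip(init - AGE_MIN, 0, len(C) - 1)] >= policy.min_pack_years - 1e-12
    lo = np.maximum.reduce([
        np.full(init.shape, policy.age_min),
        a_py,
        np.full(init.shape, policy.start_year - birth_year),
    ])
    hi = np.minimum.reduce([
        np.full(init.shape, min(policy.age_max, AGE_MAX)),
        quit + policy.max_years_since_quit,
        np.full(init.shape, policy.end_year - birth_year),
    ])
    never_ok = (init < NEVER) & attained
    hi = np.where(never_ok, hi, -1)
    lo = np.where(never_ok, lo, 0)
    return lo.astype(np.int64), hi.astype(np.int64)


def run_screening(person: Person, policy: ScreeningPolicy,
                  bundle: ParameterBundle,
                  rng: np.random.Generator) -> list[ScreenEvent]:
    """Annual screening for one person; may screen-detect their tumor.

    Emits one event per attended eligible year while alive and undiagnosed.
    Adherence is one per-person Bernoulli draw; CT sensitivity is drawn per
    visit with preclinical disease.  On detection,
    :func:`lcpm.natural_history.screen_detect_outcome` updates the tumor.
    """
    from .natural_history import screen_detect_outcome

    nh = bundle.natural_history
    history = person.smoking
    events: list[ScreenEvent] = []
    if rng.random() >= policy.adherence:
        return events
    tumor = person.tumor
    diag_age = np.inf
    if tumor is not None:
        diag_age = tumor.clinical_detection_age
        if tumor.incidental_age is not None:
            diag_age = min(diag_age, tumor.incidental_age)
    last_screen = None
    for year in range(policy.start_year, policy.end_year + 1):
        age = year - person.birth_year
        if age < AGE_MIN or age > AGE_MAX:
            continue
        if age >= min(person.oc_death_age, diag_age):
            break
        if tumor is not None and not tumor.cured_clinical \
                and age >= tumor.lc_death_age_clinical:
            break
        if not is_eligible(policy, history, age, year, bundle.smoking):
            continue
        if last_screen is not None and age - last_screen < policy.interval:
            continue
        last_screen = age
        preclinical = (tumor is not None
                       and tumor.onset_age <= age < tumor.clinical_detection_age)
        if preclinical and rng.random() < nh.ct_sensitivity:
            screen_detect_outcome(tumor, float(age), nh, rng)
            events.append(ScreenEvent(person.id, year, age, "detected"))
            break
        events.append(ScreenEvent(person.id, year, age, "negative"))
    return events


def count_screens(events: Iterable[ScreenEvent],
                  people: Optional[Sequence[Person]] = None) -> pd.DataFrame:
    """Tally screen events by (year, sex); sex requires the person list."""
    sex_of = {}
    if people is not None:
        sex_of = {p.id: p.sex for p in people}
    rows = [(e.year, sex_of.get(e.person_id, "all")) for e in events]
    if not rows:
        return pd.DataFrame(columns=["year", "sex", "screens"])
    df = pd.DataFrame(rows, columns=["year", "sex"])
    return df.groupby(["year", "sex"], as_index=False).size() \
        .rename(columns={"size": "screens"})


def eligible_fraction(n_screens: float, adult_population: float) -> float:
    """Screens divided by the adult population (same year coverage)."""
    if adult_population <= 0:
        raise ValueError("adult population must be positive")
    frac = n_screens / adult_population
    if frac < 0:
        raise ValueError("screen count must be nonnegative")
    return frac
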