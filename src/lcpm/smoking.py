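"""Smoking life-courses: initiation, cessation, pack-years, prevalence.

Each person is never / current / former at every age.  Initiation is drawn
from a cohort-specific cumulative logistic curve; current smokers face the
published annual quit probabilities (tracked from age 30 for males, 35 for
females) with no relapse; smoking intensity (cigarettes/day) is the
deterministic published profile by sex, age and calendar year.  The module
provides scalar per-person operations and the vectorized per-cohort kernels
the simulation engine uses, plus the cross-sectional prevalence estimator and
its deterministic (expected-value) counterpart used by calibration.

Time is discrete in whole years: a person who initiates at age ``a`` smokes
during ages ``a, a+1, ...``; a quit event during age ``a`` makes them former
from age ``a + 1``; ``quit_age`` records the first age as a former smoker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .parameters import (
    AGE_MAX,
    AGE_MIN,
    SmokingParameters,
    cigarettes_per_day,
    sex_index,
)

__all__ = [
    "NEVER",
    "SmokingHistory",
    "Person",
    "sample_smoking_history",
    "sample_histories_arrays",
    "pack_years",
    "smoking_status",
    "years_since_quit",
    "cumulative_cpd",
    "smoking_band",
    "cross_sectional_prevalence",
    "expected_prevalence",
]

#: sentinel age for "event never happens" in the integer array kernels
NEVER = 10_000

_AGES = np.arange(AGE_MIN, AGE_MAX + 1)


@dataclass
class SmokingHistory:
    """One person's smoking life-course."""

    sex: str
    birth_year: int
    initiation_age: Optional[int] = None
    quit_age: Optional[int] = None

    def __post_init__(self) -> None:
        if self.initiation_age is not None and self.initiation_age < AGE_MIN:
            raise ValueError("initiation_age must be >= 15")
        if self.quit_age is not None:
            if self.initiation_age is None:
                raise ValueError("quit_age without initiation_age")
            if self.quit_age <= self.initiation_age:
                raise ValueError("quit_age must exceed initiation_age")


@dataclass
class Person:
    """A simulated individual (smoking plus competing-risk attributes)."""

    id: int
    sex: str
    birth_year: int
    smoking: SmokingHistory
    oc_death_age: float = float("inf")
    tumor: object | None = None


# ---------------------------------------------------------------------------
# sampling kernels
# ---------------------------------------------------------------------------


def _initiation_cdf(sex: str, birth_year: int, params: SmokingParameters) -> np.ndarray:
    return params.initiation_params[sex].cdf(_AGES, birth_year)


def _quit_log_survival(sex: str, birth_year: int,
                       params: SmokingParameters) -> np.ndarray:
    """log P(no quit event through age 15+i), tracked-start smoker.

    Cessation is zero below the tracked start age, so the curve is flat at 0
    there; entry i sums log(1 - cessation) over ages 15..15+i.  Working in
    logs keeps certain cessation (rate 1, clipped infinitesimally) finite
    instead of underflowing the survival product to zero.
    """
    cess = np.minimum(params.cessation_curve(sex, birth_year), 1.0 - 1e-12)
    return np.cumsum(np.log1p(-cess))


def _quit_survival(sex: str, birth_year: int, params: SmokingParameters) -> np.ndarray:
    """P(no quit event through age 15+i) for a smoker tracked from the start age."""
    return np.exp(_quit_log_survival(sex, birth_year, params))


def sample_histories_arrays(sex: str, birth_year: int, n: int,
                            params: SmokingParameters,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vector kernel: (initiation_age, quit_age) for ``n`` people of a cohort.

    Returns integer ages with :data:`NEVER` marking "no such event".
    """
    cdf = _initiation_cdf(sex, birth_year, params)
    u_init = rng.random(n)
    u_quit = rng.random(n)
    init = np.where(u_init < cdf[-1],
                    AGE_MIN + np.searchsorted(cdf, u_init, side="left"),
                    NEVER).astype(np.int64)

    log_surv = _quit_log_survival(sex, birth_year, params)
    # log-survival just before each person's personal tracking start
    start = np.maximum(np.minimum(init, AGE_MAX), params.cessation_start_age(sex))
    start_idx = start - AGE_MIN
    prev = np.where(start_idx > 0, log_surv[np.maximum(start_idx - 1, 0)], 0.0)
    with np.errstate(divide="ignore"):
        threshold = np.log(u_quit) + prev
    # first age with conditional survival strictly below the uniform draw;
    # because survival is flat before the personal start this never
    # precedes it
    event_idx = np.searchsorted(-log_surv, -threshold, side="right")
    quit = np.where((init != NEVER) & (event_idx < len(log_surv)),
                    AGE_MIN + event_idx + 1, NEVER).astype(np.int64)
    return init, quit


def sample_smoking_history(sex: str, birth_year: int, params: SmokingParameters,
                           rng: np.random.Generator) -> SmokingHistory:
    """Draw a single smoking life-course."""
    init, quit = sample_histories_arrays(sex, birth_year, 1, params, rng)
    return SmokingHistory(
        sex=sex, birth_year=birth_year,
        initiation_age=None if init[0] == NEVER else int(init[0]),
        quit_age=None if quit[0] == NEVER else int(quit[0]),
    )


# ---------------------------------------------------------------------------
# pack-years and status
# ---------------------------------------------------------------------------


def cumulative_cpd(sex: str, birth_year: int,
                   params: SmokingParameters) -> np.ndarray:
    """Cohort pack accumulator: C[a - 15] = packs/day-years over ages [15, a).

    Pack-years for a person with initiation ``i`` and quit ``q`` at attained
    age ``a`` are ``C[min(a, q) - 15] - C[i - 15]``.
    """
    cpd = cigarettes_per_day(sex, _AGES, birth_year + _AGES, params)
    return np.concatenate([[0.0], np.cumsum(np.asarray(cpd) / 20.0)])


def _py_from_accumulator(C: np.ndarray, init, quit, age) -> np.ndarray:
    init = np.asarray(init)
    quit = np.asarray(quit)
    age = np.asarray(age)
    end = np.clip(np.minimum(np.minimum(age, quit), AGE_MAX + 1) - AGE_MIN,
                  0, len(C) - 1)
    start = np.clip(init - AGE_MIN, 0, len(C) - 1)
    py = C[end] - C[start]
    return np.where((init >= NEVER) | (end <= start), 0.0, py)


def pack_years(history: SmokingHistory, age: float,
               params: SmokingParameters | None = None) -> float:
    """Cumulative pack-years at an attained age (one pack = 20 cigarettes).

    Accrues cigarettes/day / 20 over each year smoked; nondecreasing in age,
    zero for never-smokers, frozen after quitting.
    """
    if age < AGE_MIN:
        raise ValueError("age must be >= 15")
    params = params or SmokingParameters()
    if history.initiation_age is None:
        return 0.0
    C = cumulative_cpd(history.sex, history.birth_year, params)
    quit = history.quit_age if history.quit_age is not None else NEVER
    return float(_py_from_accumulator(
        C, history.initiation_age, quit, int(np.floor(age))))


def smoking_status(history: SmokingHistory, age: float) -> str:
    """never / current / former at an attained age."""
    if age < AGE_MIN:
        raise ValueError("age must be >= 15")
    if history.initiation_age is None or age < history.initiation_age:
        return "never"
    if history.quit_age is None or age < history.quit_age:
        return "current"
    return "former"


def years_since_quit(history: SmokingHistory, age: float) -> Optional[float]:
    """age - quit_age for former smokers, None otherwise."""
    if smoking_status(history, age) != "former":
        return None
    return age - history.quit_age


def smoking_band(init, quit, C: np.ndarray, heavy_threshold: float = 20.0) -> np.ndarray:
    """Other-cause-mortality intensity band: 0 never, 1 light, 2 heavy.

    Ever-smokers are classified by mean cigarettes/day over their smoked
    years (heavy at or above ``heavy_threshold``).
    """
    init = np.asarray(init)
    quit = np.asarray(quit)
    end = np.minimum(quit, AGE_MAX + 1)
    years = np.maximum(end - init, 1)
    packs = _py_from_accumulator(C, init, quit, np.full(init.shape, AGE_MAX + 1))
    mean_cpd = 20.0 * packs / years
    band = np.where(init >= NEVER, 0, np.where(mean_cpd >= heavy_threshold, 2, 1))
    return band.astype(np.int64)


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def cross_sectional_prevalence(cohorts: Iterable, sex: str, year: int,
                               age_range: tuple[int, int] = (35, 74)) -> float:
    """Fraction of alive people in an age range who currently smoke.

    ``cohorts`` is an iterable of simulated cohort states exposing ``sex``,
    ``birth_year`` and per-person arrays ``init``, ``quit`` and ``oc_death``
    (ages; :data:`NEVER` sentinels), optionally ``lc_death``.  A person is in
    the cross-section if their attained age in ``year`` falls inside
    ``age_range`` and they have not yet died.
    """
    lo, hi = age_range
    current = 0
    alive = 0
    for state in cohorts:
        if getattr(state, "sex") != sex:
            continue
        age = year - state.birth_year
        if age < lo or age > hi:
            continue
        alive_mask = np.asarray(state.oc_death) > age
        lc_death = getattr(state, "lc_death", None)
        if lc_death is not None:
            alive_mask = alive_mask & (np.asarray(lc_death) > age)
        alive += int(alive_mask.sum())
        current += int((alive_mask
                        & (np.asarray(state.init) <= age)
                        & (np.asarray(state.quit) > age)).sum())
    if alive == 0:
        raise ValueError(f"no simulated {sex} aged {lo}-{hi} alive in {year}")
    return current / alive


def expected_prevalence(smoking: SmokingParameters, oc_survival,
                        sex: str, year: int,
                        age_range: tuple[int, int] = (35, 74),
                        heavy_threshold: float = 20.0) -> float:
    """Deterministic expected current-smoker prevalence.

    Closed-form expectation of :func:`cross_sectional_prevalence` under the
    sampling model (equal numbers simulated per cohort), including the
    differential other-cause survival of ever-smokers.  ``oc_survival(sex,
    band)`` must return cumulative survival through each age 15..84, as from
    :meth:`lcpm.natural_history.LifeTable.survival_curve`.

    This is the smoking-calibration objective: it is smooth and free of
    Monte-Carlo noise, and the microsimulation reproduces it within sampling
    error (lung-cancer deaths, ignored here, remove well under 1% of the
    cross-section in the target years).
    """
    sex_index(sex)
    lo, hi = age_range
    tracked = smoking.cessation_start_age(sex)
    # alive-through-age weights per band, with a leading 1 so that index
    # a - 15 + 1 is P(death age > a)
    alive = [np.concatenate([[1.0], np.asarray(oc_survival(sex, b), float)])
             for b in range(3)]
    num = 0.0
    den = 0.0
    for age in range(lo, hi + 1):
        birth_year = year - age
        a_idx = age - AGE_MIN
        cdf = _initiation_cdf(sex, birth_year, smoking)
        f = np.diff(np.concatenate([[0.0], cdf]))[: a_idx + 1]
        init_ages = _AGES[: a_idx + 1]
        qs_full = np.concatenate([[1.0], _quit_survival(sex, birth_year, smoking)])
        start = np.maximum(init_ages, tracked)
        # current at `age` <=> no quit event during ages [start, age - 1]
        cond_current = qs_full[a_idx] / qs_full[np.clip(start - AGE_MIN, 0, a_idx)]
        C = cumulative_cpd(sex, birth_year, smoking)
        band = smoking_band(init_ages, np.full_like(init_ages, NEVER), C,
                            heavy_threshold)
        alive_t = np.array([alive[b][a_idx + 1] for b in band])
        num += float(np.sum(f * cond_current * alive_t))
        den += float((1.0 - cdf[a_idx]) * alive[0][a_idx + 1]
                     + np.sum(f * alive_t))
    return num / den
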