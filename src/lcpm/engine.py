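"""Cohort simulation engine: scenarios, common random numbers, outcomes.

Each model run simulates closed birth cohorts (everyone enters at age 15 and
exits at 85) whose members carry a smoking life-course, an other-cause death
age and, possibly, a latent lung cancer.  Tallies of lung-cancer deaths,
person-years, screens and eligible people are accumulated per (birth cohort,
calendar year 1975-2050, sex, smoking status) and scaled to a population
projection.

Common random numbers: every random stream is seeded by (seed, sex, birth
year, stream index), so two scenarios run with the same seed share identical
people, smoking histories, tumors and other-cause deaths — only events
downstream of screening differ.  Screening-specific draws (adherence,
per-visit sensitivity, screen-stage) are likewise policy-independent, so a
policy change re-uses the same draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    AGE_MAX,
    AGE_MIN,
    ParameterBundle,
    ScreeningPolicy,
    SEXES,
    SMOKING_STATUSES,
    YEAR_MAX,
    YEAR_MIN,
)
from .natural_history import (
    LifeTable,
    incidental_delay_years,
    sample_oc_death_ages,
    sample_onset_ages,
    unit_hazard_matrix,
)
from .screening import eligibility_bounds
from .smoking import NEVER, cumulative_cpd, sample_histories_arrays, smoking_band

__all__ = [
    "COHORT_MIN",
    "COHORT_MAX",
    "CohortState",
    "PolicyOutcome",
    "ScenarioResult",
    "build_cohort_state",
    "apply_policy",
    "simulate_scenario",
    "compare_scenarios",
    "scale_results",
    "mortality_reduction",
    "life_years_saved",
    "per_death",
    "screens_per_death_prevented",
]

#: cohorts contributing anyone aged 15-84 during 1975-2050
COHORT_MIN = YEAR_MIN - AGE_MAX  # 1891
COHORT_MAX = YEAR_MAX - AGE_MIN  # 2035

_YEARS = np.arange(YEAR_MIN, YEAR_MAX + 1)
_N_YEARS = len(_YEARS)
_EXIT_AGE = AGE_MAX + 1

# stream indices for per-cohort seeding
_STREAM_SMOKING, _STREAM_OC, _STREAM_NH, _STREAM_SCREEN = 0, 1, 2, 3


def _rng(seed: int, sex_idx: int, birth_year: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(sex_idx, birth_year, stream))
    return np.random.default_rng(ss)


@dataclass
class CohortState:
    """All person-level arrays for one (sex, birth-year) cohort."""

    sex: str
    sex_idx: int
    birth_year: int
    n: int
    init: np.ndarray
    quit: np.ndarray
    band: np.ndarray
    oc_death: np.ndarray
    C: np.ndarray  # cohort pack accumulator
    onset: np.ndarray
    clin_detect: np.ndarray
    inc_age: np.ndarray
    diag_base: np.ndarray
    stage_clinical: np.ndarray
    hist_idx: np.ndarray
    cured_clinical: np.ndarray
    sojourn: np.ndarray
    survival: np.ndarray
    lc_clin: np.ndarray
    u_cure: np.ndarray
    u_screen_stage: np.ndarray
    u_adherence: np.ndarray
    u_sensitivity: np.ndarray
    exp_onset: Optional[np.ndarray] = None
    lam_unit: Optional[np.ndarray] = None

    @property
    def lc_death(self) -> np.ndarray:
        """Baseline (no-screening) lung-cancer death age; inf when none."""
        return self.lc_clin


def build_cohort_state(sex: str, birth_year: int, n: int,
                       bundle: ParameterBundle, life_table: LifeTable,
                       seed: int, with_tumors: bool = True,
                       keep_hazard: bool = False) -> CohortState:
    """Simulate the policy-independent life histories of one cohort."""
    sex_idx = SEXES.index(sex)
    nh = bundle.natural_history
    smoking = bundle.smoking

    rng_s = _rng(seed, sex_idx, birth_year, _STREAM_SMOKING)
    init, quit = sample_histories_arrays(sex, birth_year, n, smoking, rng_s)
    C = cumulative_cpd(sex, birth_year, smoking)
    band = smoking_band(init, quit, C, bundle.other_cause.heavy_cpd_threshold)

    rng_o = _rng(seed, sex_idx, birth_year, _STREAM_OC)
    oc_death = sample_oc_death_ages(sex, band, life_table, rng_o.random(n))

    inf = np.full(n, np.inf)
    state = CohortState(
        sex=sex, sex_idx=sex_idx, birth_year=birth_year, n=n,
        init=init, quit=quit, band=band, oc_death=oc_death, C=C,
        onset=np.full(n, NEVER, dtype=np.int64), clin_detect=inf.copy(),
        inc_age=inf.copy(), diag_base=inf.copy(),
        stage_clinical=np.full(n, -1, dtype=np.int64),
        hist_idx=np.full(n, -1, dtype=np.int64),
        cured_clinical=np.zeros(n, dtype=bool),
        sojourn=np.zeros(n), survival=np.zeros(n), lc_clin=inf.copy(),
        u_cure=np.zeros(n), u_screen_stage=np.zeros(n),
        u_adherence=np.zeros(n), u_sensitivity=np.zeros(n),
    )
    if not with_tumors:
        return state

    rng_n = _rng(seed, sex_idx, birth_year, _STREAM_NH)
    exp_onset = rng_n.exponential(size=n)
    u_soj = rng_n.random(n)
    u_hist = rng_n.random(n)
    u_stage = rng_n.random(n)
    u_cure = rng_n.random(n)
    u_surv = rng_n.random(n)
    u_inc = rng_n.random(n)

    lam = unit_hazard_matrix(sex, birth_year, init, quit, bundle)
    onset = sample_onset_ages(lam, nh.baseline_level[sex], exp_onset, oc_death)
    has = onset < NEVER

    sojourn = -nh.sojourn_mean_years * np.log1p(-u_soj)
    clin_detect = np.where(has, onset + sojourn, np.inf)
    delay = incidental_delay_years(np.maximum(u_inc, 1e-300),
                                   nh.incidental_detection_rate)
    inc_age = np.where(has, onset + delay, np.inf)
    inc_ok = has & (inc_age < clin_detect) & (inc_age < oc_death) & (inc_age <= AGE_MAX)
    inc_age = np.where(inc_ok, inc_age, np.inf)
    diag_base = np.minimum(clin_detect, inc_age)

    # histology by diagnosis period
    detect_year = np.where(has, birth_year + clin_detect, 2001.0)
    hist_idx = np.zeros(n, dtype=np.int64)
    for lo_y, hi_y, period in ((-np.inf, 1995, "1991-1995"),
                               (1996, 2000, "1996-2000"),
                               (2001, np.inf, "2001-2005")):
        mask = (np.floor(detect_year) >= lo_y) & (np.floor(detect_year) <= hi_y)
        if mask.any():
            cum = np.cumsum(bundle.histology.distribution(sex, period))
            hist_idx[mask] = np.searchsorted(cum, u_hist[mask], side="left")

    cum_clin = np.cumsum(nh.stage_distribution_clinical)
    stage = np.searchsorted(cum_clin, u_stage, side="left").clip(0, 3)
    cure = np.asarray(nh.cure_fraction)
    cured = u_cure < cure[stage]
    surv_mean = np.asarray(nh.survival_mean_years)
    survival = -surv_mean[stage] * np.log1p(-u_surv)
    lc_clin = np.where(has & ~cured, clin_detect + survival, np.inf)

    rng_c = _rng(seed, sex_idx, birth_year, _STREAM_SCREEN)
    state.u_adherence = rng_c.random(n)
    state.u_sensitivity = rng_c.random(n)
    state.u_screen_stage = rng_c.random(n)

    state.onset = onset
    state.clin_detect = clin_detect
    state.inc_age = inc_age
    state.diag_base = diag_base
    # stage/histology/cure draws are kept for everyone (not only people whose
    # onset materialized) so calibration can reason about counterfactual onsets
    state.stage_clinical = stage
    state.hist_idx = hist_idx
    state.cured_clinical = has & cured
    state.sojourn = sojourn
    state.survival = survival
    state.lc_clin = lc_clin
    state.u_cure = u_cure
    if keep_hazard:
        state.lam_unit = lam
        state.exp_onset = exp_onset
    return state


@dataclass
class PolicyOutcome:
    """Scenario-dependent per-person outcomes for one cohort."""

    lc_death: np.ndarray
    death_age: np.ndarray  # min(other-cause, lung cancer, exit)
    cause_lc: np.ndarray
    diag_age: np.ndarray
    detected: np.ndarray
    detect_age: np.ndarray
    elig_lo: np.ndarray
    elig_hi: np.ndarray
    attends: np.ndarray


def apply_policy(state: CohortState, policy: Optional[ScreeningPolicy],
                 bundle: ParameterBundle) -> PolicyOutcome:
    """Evaluate (screen-detect and re-outcome) one policy on a cohort.

    With ``policy=None`` this is the no-screening baseline.  All screening
    draws come from policy-independent per-person uniforms, so outcomes
    under different policies are exactly coupled.
    """
    nh = bundle.natural_history
    n = state.n
    oc = state.oc_death
    if policy is None:
        lc = state.lc_clin
        death = np.minimum(np.minimum(oc, lc), _EXIT_AGE)
        return PolicyOutcome(
            lc_death=lc, death_age=death,
            cause_lc=(lc < oc) & (lc < _EXIT_AGE),
            diag_age=state.diag_base,
            detected=np.zeros(n, dtype=bool),
            detect_age=np.full(n, np.inf),
            elig_lo=np.zeros(n, dtype=np.int64),
            elig_hi=np.full(n, -1, dtype=np.int64),
            attends=np.zeros(n, dtype=bool),
        )

    lo, hi = eligibility_bounds(policy, state.birth_year, state.init,
                                state.quit, state.C)
    attends = state.u_adherence < policy.adherence
    k = policy.interval

    sens = nh.ct_sensitivity
    if sens >= 1.0:
        g = np.ones(n)
    elif sens <= 0.0:
        g = np.full(n, np.inf)
    else:
        g = 1.0 + np.floor(np.log(np.maximum(state.u_sensitivity, 1e-300))
                           / np.log1p(-sens))

    has = state.onset < NEVER
    pre_lo = np.maximum(lo, np.where(has, state.onset, NEVER))
    pre_hi = np.minimum.reduce([
        hi.astype(float),
        np.ceil(state.diag_base) - 1,
        oc.astype(float) - 1,
    ])
    j_lo = np.ceil((pre_lo - lo) / k)
    j_hi = np.floor((pre_hi - lo) / k)
    m = np.where(has & (j_hi >= j_lo), j_hi - j_lo + 1, 0.0)
    detected = attends & (m >= 1) & (g <= m)
    detect_age = np.where(detected, lo + (j_lo + g - 1) * k, np.inf)

    cum_screen = np.cumsum(nh.stage_distribution_screen())
    stage_screen = np.searchsorted(cum_screen, state.u_screen_stage,
                                   side="left").clip(0, 3)
    cure = np.asarray(nh.cure_fraction)
    clin_stage = np.clip(state.stage_clinical, 0, 3)
    cure_eff = np.maximum(cure[clin_stage], cure[stage_screen])
    cured_screen = detected & (state.u_cure < cure_eff)

    lc = np.where(cured_screen, np.inf, state.lc_clin)
    diag = np.where(detected, detect_age, state.diag_base)
    death = np.minimum(np.minimum(oc, lc), _EXIT_AGE)
    return PolicyOutcome(
        lc_death=lc, death_age=death,
        cause_lc=(lc < oc) & (lc < _EXIT_AGE),
        diag_age=diag, detected=detected, detect_age=detect_age,
        elig_lo=lo, elig_hi=hi, attends=attends,
    )


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    """Per (cohort, calendar year, sex, smoking status) tallies of one run.

    ``deaths`` are lung-cancer deaths (status at death); ``person_years``
    count whole years lived at ages 15-84; ``screens`` and ``eligible``
    are CT exams and screen-eligible people per year (status at that year).
    """

    policy_name: str
    cohorts: np.ndarray
    n_per_cohort: int
    deaths: np.ndarray        # (C, Y, 2, 3)
    person_years: np.ndarray  # (C, Y, 2, 3)
    screens: np.ndarray       # (C, Y, 2, 3)
    eligible: np.ndarray      # (C, Y, 2, 3)
    scaled: bool = False
    scale_factors: Optional[np.ndarray] = None  # (C, 2)
    years: np.ndarray = field(default_factory=lambda: _YEARS.copy())

    @classmethod
    def empty(cls, policy_name: str, cohorts: Sequence[int],
              n_per_cohort: int) -> "ScenarioResult":
        cohorts = np.asarray(sorted(cohorts))
        shape = (len(cohorts), _N_YEARS, len(SEXES), len(SMOKING_STATUSES))
        return cls(policy_name=policy_name, cohorts=cohorts,
                   n_per_cohort=n_per_cohort,
                   deaths=np.zeros(shape), person_years=np.zeros(shape),
                   screens=np.zeros(shape), eligible=np.zeros(shape))

    @classmethod
    def from_status_totals(cls, policy_name: str,
                           deaths: Mapping[tuple[str, str], float],
                           person_years: Mapping[str, float] | None = None,
                           screens: Mapping[str, float] | None = None,
                           ) -> "ScenarioResult":
        """Wrap aggregate (sex, status) tally tables as a one-cohort result.

        Used to push printed outcome tables through the same reduction /
        life-years / screens arithmetic as simulated results; all mass is
        placed in the first year of the policy window.
        """
        res = cls.empty(policy_name, cohorts=[1960], n_per_cohort=1)
        y = int(np.searchsorted(res.years, 2016))
        for (sex, status), v in deaths.items():
            res.deaths[0, y, SEXES.index(sex), SMOKING_STATUSES.index(status)] = v
        for mapping, arr in ((person_years, res.person_years),
                             (screens, res.screens)):
            if mapping:
                for sex, v in mapping.items():
                    arr[0, y, SEXES.index(sex), 0] = v
        return res

    # -- selection helpers -------------------------------------------------

    def _window(self, years: tuple[int, int]) -> slice:
        lo = int(np.searchsorted(self.years, years[0]))
        hi = int(np.searchsorted(self.years, years[1], side="right"))
        return slice(lo, hi)

    def _reduce(self, arr: np.ndarray, years: tuple[int, int],
                sex: Optional[str], status: Optional[str]) -> float:
        sel = arr[:, self._window(years)]
        if sex is not None:
            sel = sel[:, :, [SEXES.index(sex)]]
        if status is not None:
            sel = sel[..., [SMOKING_STATUSES.index(status)]]
        return float(sel.sum())

    def total_deaths(self, years=(2016, YEAR_MAX), sex=None, status=None) -> float:
        return self._reduce(self.deaths, years, sex, status)

    def total_person_years(self, years=(2016, YEAR_MAX), sex=None, status=None) -> float:
        return self._reduce(self.person_years, years, sex, status)

    def total_screens(self, years=(2016, YEAR_MAX), sex=None, status=None) -> float:
        return self._reduce(self.screens, years, sex, status)

    def total_eligible(self, years=(2016, YEAR_MAX), sex=None, status=None) -> float:
        return self._reduce(self.eligible, years, sex, status)

    def by_year(self, quantity: str = "deaths", sex=None, status=None) -> pd.Series:
        arr = getattr(self, quantity)
        if sex is not None:
            arr = arr[:, :, [SEXES.index(sex)]]
        if status is not None:
            arr = arr[..., [SMOKING_STATUSES.index(status)]]
        return pd.Series(arr.sum(axis=(0, 2, 3)), index=pd.Index(self.years, name="year"),
                         name=quantity)

    def deaths_by_cohort(self, sex=None) -> pd.Series:
        arr = self.deaths
        if sex is not None:
            arr = arr[:, :, [SEXES.index(sex)]]
        return pd.Series(arr.sum(axis=(1, 2, 3)),
                         index=pd.Index(self.cohorts, name="birth_year"), name="deaths")

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (year, sex, smoking_status)."""
        rows = []
        for yi, year in enumerate(self.years):
            for si, sex in enumerate(SEXES):
                for ti, status in enumerate(SMOKING_STATUSES):
                    rows.append((int(year), sex, status,
                                 float(self.deaths[:, yi, si, ti].sum()),
                                 float(self.person_years[:, yi, si, ti].sum()),
                                 float(self.screens[:, yi, si, ti].sum()),
                                 float(self.eligible[:, yi, si, ti].sum())))
        return pd.DataFrame(rows, columns=[
            "year", "sex", "smoking_status", "lc_deaths", "person_years",
            "screens", "eligible"])

    def save_csv(self, path, seed: Optional[int] = None) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# policy={self.policy_name} n_per_cohort={self.n_per_cohort}"
                     f" scaled={self.scaled}"
                     + (f" seed={seed}" if seed is not None else "") + "\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.6f")


def _interval_tally(acc: np.ndarray, birth_year: int, lo: np.ndarray,
                    hi: np.ndarray, weight: float = 1.0) -> None:
    """Add 1 per (person, year) for attained ages in [lo, hi] into acc (Y,)."""
    ylo = np.clip(birth_year + lo - YEAR_MIN, 0, _N_YEARS)
    yhi = np.clip(birth_year + hi - YEAR_MIN + 1, 0, _N_YEARS)
    valid = yhi > ylo
    if not valid.any():
        return
    diff = (np.bincount(ylo[valid], minlength=_N_YEARS + 1)
            - np.bincount(yhi[valid], minlength=_N_YEARS + 1))
    acc += weight * np.cumsum(diff[:_N_YEARS])


def _tally_cohort(result: ScenarioResult, state: CohortState,
                  outcome: PolicyOutcome, policy: Optional[ScreeningPolicy],
                  bundle: ParameterBundle) -> None:
    ci = int(np.searchsorted(result.cohorts, state.birth_year))
    si = state.sex_idx
    by = state.birth_year
    death = outcome.death_age
    last_lived = np.ceil(death).astype(np.int64) - 1  # last whole age lived
    last_lived = np.minimum(last_lived, AGE_MAX)
    init = np.minimum(state.init, _EXIT_AGE)
    quit = np.minimum(state.quit, _EXIT_AGE)

    # person-years by status
    _interval_tally(result.person_years[ci, :, si, 0], by,
                    np.full(state.n, AGE_MIN),
                    np.minimum(init - 1, last_lived))
    _interval_tally(result.person_years[ci, :, si, 1], by,
                    init, np.minimum(quit - 1, last_lived))
    _interval_tally(result.person_years[ci, :, si, 2], by,
                    quit, last_lived)

    # lung-cancer deaths by status at death
    lc = outcome.lc_death
    died = outcome.cause_lc
    if died.any():
        age_at = np.floor(lc[died]).astype(np.int64)
        year_idx = by + age_at - YEAR_MIN
        ok = (year_idx >= 0) & (year_idx < _N_YEARS)
        status = np.where(age_at < state.init[died], 0,
                          np.where(age_at < state.quit[died], 1, 2))
        for ti in range(3):
            mask = ok & (status == ti)
            if mask.any():
                result.deaths[ci, :, si, ti] += np.bincount(
                    year_idx[mask], minlength=_N_YEARS)

    if policy is None:
        return

    # screens and eligible people, per calendar year, by current/former status
    lo, hi = outcome.elig_lo, outcome.elig_hi
    diag = outcome.diag_age
    det = outcome.detected
    ds = outcome.detect_age
    k = policy.interval
    for year in range(max(policy.start_year, by + AGE_MIN),
                      min(policy.end_year, by + AGE_MAX) + 1):
        age = year - by
        undiag = (age < diag) | (det & (age == ds))
        elig_now = (lo <= age) & (age <= hi) & (age < death) & undiag
        if not elig_now.any():
            continue
        status_now = np.where(age < state.quit, 1, 2)
        yi = year - YEAR_MIN
        screened = elig_now & outcome.attends & ((age - lo) % k == 0)
        for ti in (1, 2):
            smask = status_now == ti
            result.eligible[ci, yi, si, ti] += int((elig_now & smask).sum())
            result.screens[ci, yi, si, ti] += int((screened & smask).sum())


# ---------------------------------------------------------------------------
# scenario drivers
# ---------------------------------------------------------------------------


def _cohort_range(cohorts) -> list[int]:
    if cohorts is None:
        return list(range(COHORT_MIN, COHORT_MAX + 1))
    return sorted(int(c) for c in cohorts)


def simulate_scenario(policy: Optional[ScreeningPolicy], bundle: ParameterBundle,
                      life_table: LifeTable, n_per_cohort: int, seed: int,
                      cohorts: Optional[Iterable[int]] = None,
                      with_tumors: bool = True) -> ScenarioResult:
    """Run one scenario (``policy=None`` = no screening) over all cohorts."""
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
    cohort_list = _cohort_range(cohorts)
    name = policy.name if policy is not None else "baseline"
    result = ScenarioResult.empty(name, cohort_list, n_per_cohort)
    for sex in SEXES:
        for by in cohort_list:
            state = build_cohort_state(sex, by, n_per_cohort, bundle,
                                       life_table, seed, with_tumors=with_tumors)
            outcome = apply_policy(state, policy, bundle)
            _tally_cohort(result, state, outcome, policy, bundle)
    return result


def compare_scenarios(policies: Mapping[str, Optional[ScreeningPolicy]],
                      bundle: ParameterBundle, life_table: LifeTable,
                      n_per_cohort: int, seed: int,
                      cohorts: Optional[Iterable[int]] = None,
                      ) -> dict[str, ScenarioResult]:
    """Run several policies over shared person histories (one build per cohort).

    Structurally identical to calling :func:`simulate_scenario` per policy
    with the same seed, but ~P times cheaper for P policies.
    """
    cohort_list = _cohort_range(cohorts)
    results = {name: ScenarioResult.empty(
        policy.name if policy is not None else "baseline", cohort_list, n_per_cohort)
        for name, policy in policies.items()}
    for sex in SEXES:
        for by in cohort_list:
            state = build_cohort_state(sex, by, n_per_cohort, bundle,
                                       life_table, seed)
            for name, policy in policies.items():
                outcome = apply_policy(state, policy, bundle)
                _tally_cohort(results[name], state, outcome, policy, bundle)
    return results


def scale_results(result: ScenarioResult, projection) -> ScenarioResult:
    """Scale simulated tallies to population units at cohort entry.

    Each cohort's scale factor is the projected population at its entry point
    (age 15 in the entry year, or its attained age in 1975 for cohorts
    already older) divided by the number simulated.
    """
    factors = np.zeros((len(result.cohorts), len(SEXES)))
    for i, by in enumerate(result.cohorts):
        entry_year = max(YEAR_MIN, int(by) + AGE_MIN)
        entry_age = entry_year - int(by)
        for si, sex in enumerate(SEXES):
            factors[i, si] = projection.at(entry_year, entry_age, sex) / result.n_per_cohort
    f = factors[:, None, :, None]
    return dataclasses.replace(
        result,
        deaths=result.deaths * f,
        person_years=result.person_years * f,
        screens=result.screens * f,
        eligible=result.eligible * f,
        scaled=True, scale_factors=factors,
    )


# ---------------------------------------------------------------------------
# outcome measures
# ---------------------------------------------------------------------------


def mortality_reduction(baseline: ScenarioResult, scenario: ScenarioResult,
                        years: tuple[int, int] = (2016, YEAR_MAX),
                        sex: Optional[str] = None,
                        status: Optional[str] = None) -> float:
    """(baseline deaths - scenario deaths) / baseline deaths over a window."""
    b = baseline.total_deaths(years, sex, status)
    s = scenario.total_deaths(years, sex, status)
    if b <= 0:
        raise ZeroDivisionError("no baseline lung-cancer deaths in stratum")
    return (b - s) / b


def life_years_saved(baseline: ScenarioResult, scenario: ScenarioResult,
                     years: tuple[int, int] = (2016, YEAR_MAX),
                     sex: Optional[str] = None) -> float:
    """Extra person-years lived under the scenario (undiscounted)."""
    return (scenario.total_person_years(years, sex)
            - baseline.total_person_years(years, sex))


def per_death(life_years: float, deaths_prevented: float) -> float:
    """Life-years saved per lung-cancer death prevented."""
    if deaths_prevented <= 0:
        raise ZeroDivisionError("no deaths prevented; ratio undefined")
    return life_years / deaths_prevented


def screens_per_death_prevented(result: ScenarioResult, baseline: ScenarioResult,
                                years: tuple[int, int] = (2016, YEAR_MAX),
                                sex: Optional[str] = None) -> float:
    """Total screening CT exams per lung-cancer death prevented."""
    prevented = baseline.total_deaths(years, sex) - result.total_deaths(years, sex)
    if prevented <= 0:
        raise ZeroDivisionError("no deaths prevented in stratum; ratio undefined")
    return result.total_screens(years, sex) / prevented
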