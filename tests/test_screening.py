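"""Eligibility rules and the annual CT process."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lcpm
from lcpm.natural_history import Tumor
from lcpm.parameters import ScreeningPolicy, cms_policy, cng_policy
from lcpm.screening import (
    ScreenEvent,
    count_screens,
    eligible_fraction,
    eligibility_bounds,
    is_eligible,
    run_screening,
)
from lcpm.smoking import NEVER, Person, SmokingHistory, cumulative_cpd, pack_years

from conftest import make_flat_cpd_params

FLAT20 = make_flat_cpd_params(20.0)  # one pack/day -> pack-years = years smoked


def _person(init=None, quit=None, by=1950, sex="male", oc=85.0, pid=0):
    return Person(id=pid, sex=sex, birth_year=by,
                  smoking=SmokingHistory(sex, by, init, quit), oc_death_age=oc)


class TestIsEligible:
    def test_cms_current_heavy_smoker(self):
        # 35 pack-years at 60 (one pack/day since 25), current smoker
        p = _person(init=25)
        assert is_eligible(cms_policy(), p, 60, 2016, FLAT20)

    def test_cms_quit_window_exceeded(self):
        # two packs/day from 20 to 44 (48 pack-years) but quit 16 years ago
        flat40 = make_flat_cpd_params(40.0)
        p = _person(init=20, quit=60 - 16)
        assert not is_eligible(cms_policy(), p, 60, 2016, flat40)
        # inclusive boundary: exactly 15 years since quitting still qualifies
        p = _person(init=20, quit=60 - 15)
        assert is_eligible(cms_policy(), p, 60, 2016, flat40)

    def test_cng_includes_younger_lighter_smokers_cms_excludes(self):
        # current smoker, age 52, 22 pack-years (init 30, one pack/day)
        p = _person(init=30)
        assert is_eligible(cng_policy(), p, 52, 2016, FLAT20)
        assert not is_eligible(cms_policy(), p, 52, 2016, FLAT20)

    def test_never_smoker_always_ineligible(self):
        p = _person()
        for age in range(50, 78):
            assert not is_eligible(cms_policy(), p, age, 2016, FLAT20)
            assert not is_eligible(cng_policy(), p, age, 2016, FLAT20)

    def test_outside_program_years(self):
        p = _person(init=20)
        assert not is_eligible(cms_policy(), p, 60, 2015, FLAT20)
        assert not is_eligible(cms_policy(), p, 60, 2051, FLAT20)

    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(init=st.integers(15, 70), dur=st.integers(1, 60) | st.none(),
           age=st.integers(15, 84),
           age_min=st.integers(45, 60), width=st.integers(5, 30),
           min_py=st.floats(0, 45), max_ysq=st.integers(0, 20))
    def test_matches_brute_force_rule(self, init, dur, age, age_min, width,
                                      min_py, max_ysq):
        """The implementation agrees with a literal re-statement of the rule."""
        by = 1950
        quit = None if dur is None else min(init + dur, 85)
        policy = ScreeningPolicy(name="x", age_min=age_min,
                                 age_max=age_min + width,
                                 min_pack_years=min_py,
                                 max_years_since_quit=max_ysq)
        h = SmokingHistory("male", by, init, quit)
        year = by + age
        got = is_eligible(policy, h, age, year, FLAT20)
        # independent evaluation from the rule text
        in_program = policy.start_year <= year <= policy.end_year
        in_ages = age_min <= age <= age_min + width
        ever = init <= age
        current = ever and (quit is None or age < quit)
        former_ok = current or (ever and (age - quit) <= max_ysq)
        py = pack_years(h, age, FLAT20)
        expected = (in_program and in_ages and ever and py >= min_py
                    and former_ok)
        assert got == expected

    def test_vector_bounds_agree_with_scalar_rule(self, bundle):
        rng = np.random.default_rng(11)
        by = 1955
        n = 300
        init = np.where(rng.random(n) < 0.8,
                        rng.integers(15, 60, n), NEVER).astype(np.int64)
        quit = np.where((init < NEVER) & (rng.random(n) < 0.5),
                        init + rng.integers(1, 40, n), NEVER).astype(np.int64)
        quit = np.minimum(quit, np.where(quit < NEVER, 85, NEVER))
        C = cumulative_cpd("male", by, bundle.smoking)
        for policy in (cms_policy(), cng_policy()):
            lo, hi = eligibility_bounds(policy, by, init, quit, C)
            for i in range(n):
                h = SmokingHistory(
                    "male", by,
                    None if init[i] == NEVER else int(init[i]),
                    None if quit[i] >= NEVER else int(quit[i]))
                for age in range(policy.age_min - 2, policy.age_max + 3):
                    year = by + age
                    if not (2016 <= year <= 2050):
                        continue
                    expected = is_eligible(policy, h, age, year, bundle.smoking)
                    got = bool(lo[i] <= age <= hi[i])
                    assert got == expected, (i, age, init[i], quit[i])


class TestRunScreening:
    def _with_tumor(self, onset=58.0, clin=64.0, **kw):
        kw.setdefault("by", 1955)  # screening years 2016+ reach ages 61+
        p = _person(init=20, **kw)
        p.tumor = Tumor(onset_age=onset, histology="squamous",
                        clinical_detection_age=clin, stage_clinical="IV",
                        lc_death_age_clinical=clin + 1.0, cured_clinical=False)
        p.tumor._u_cure = 0.5
        return p

    def test_zero_adherence_no_events(self, bundle):
        pol = cms_policy(adherence=0.0)
        p = self._with_tumor()
        assert run_screening(p, pol, bundle, np.random.default_rng(0)) == []

    def test_never_smoker_no_events(self, bundle):
        p = _person()
        for pol in (cms_policy(), cng_policy()):
            assert run_screening(p, pol, bundle, np.random.default_rng(0)) == []

    def test_detection_updates_tumor_and_stops(self, bundle):
        b = bundle.replace(smoking=FLAT20)
        nh = dataclasses.replace(b.natural_history, ct_sensitivity=1.0)
        b = b.replace(natural_history=nh)
        p = self._with_tumor()
        events = run_screening(p, cms_policy(), b, np.random.default_rng(0))
        detected = [e for e in events if e.result == "detected"]
        assert len(detected) == 1
        assert detected[0] is events[-1]
        assert p.tumor.detection_age == detected[0].age
        assert p.tumor.lc_death_age_screen is not None
        # screen detection happened in the preclinical window
        assert p.tumor.onset_age <= detected[0].age < p.tumor.clinical_detection_age

    def test_no_events_after_death_or_diagnosis(self, bundle):
        b = bundle.replace(smoking=FLAT20)
        nh = dataclasses.replace(b.natural_history, ct_sensitivity=0.0)
        b = b.replace(natural_history=nh)
        p = self._with_tumor(oc=68.0)
        events = run_screening(p, cms_policy(), b, np.random.default_rng(0))
        for e in events:
            assert e.age < min(p.oc_death_age, p.tumor.clinical_detection_age)

    def test_zero_sensitivity_reproduces_baseline_bit_for_bit(
            self, bundle, life_table):
        from lcpm.engine import apply_policy, build_cohort_state
        nh = dataclasses.replace(bundle.natural_history, ct_sensitivity=0.0)
        b = bundle.replace(natural_history=nh)
        state = build_cohort_state("male", 1955, 10_000, b, life_table, seed=2)
        base = apply_policy(state, None, b)
        scen = apply_policy(state, b.policies["cms"], b)
        assert np.array_equal(base.lc_death, scen.lc_death)
        assert np.array_equal(base.death_age, scen.death_age)
        assert not scen.detected.any()

    def test_halving_adherence_halves_screens(self, bundle, life_table):
        from lcpm.engine import simulate_scenario
        cohorts = range(1945, 1991)
        full = simulate_scenario(cms_policy(adherence=1.0), bundle, life_table,
                                 5_000, seed=3, cohorts=cohorts)
        half = simulate_scenario(cms_policy(adherence=0.5), bundle, life_table,
                                 5_000, seed=3, cohorts=cohorts)
        ratio = half.total_screens() / full.total_screens()
        assert ratio == pytest.approx(0.5, rel=0.03)


class TestCounting:
    def test_zero_events_empty_table(self):
        assert count_screens([]).empty

    def test_tally_by_year_and_sex(self):
        people = [_person(pid=0), _person(pid=1, sex="female")]
        events = [ScreenEvent(0, 2016, 60, "negative"),
                  ScreenEvent(0, 2017, 61, "negative"),
                  ScreenEvent(1, 2016, 60, "detected")]
        df = count_screens(events, people)
        total = dict(zip(zip(df.year, df.sex), df.screens))
        assert total == {(2016, "male"): 1, (2017, "male"): 1,
                         (2016, "female"): 1}

    def test_eligible_fraction_arithmetic(self):
        assert eligible_fraction(100, 10_000) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            eligible_fraction(10, 0)
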