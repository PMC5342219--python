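"""Natural history: onset hazard, detection channels, survival, life tables."""

import dataclasses
import math

import numpy as np
import pytest

import lcpm
from lcpm.natural_history import (
    LifeTable,
    Tumor,
    incidental_delay_years,
    lung_cancer_hazard,
    other_cause_death_age,
    sample_oc_death_ages,
    sample_tumor,
    screen_detect_outcome,
)
from lcpm.smoking import NEVER, Person, SmokingHistory
from lcpm.synthetic import generate_life_tables

from conftest import make_flat_cpd_params


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestHazard:
    def test_never_smoker_exactly_baseline(self, bundle):
        nh = bundle.natural_history
        h = SmokingHistory("male", 1950)
        for age in (40, 60, 80):
            assert lung_cancer_hazard(age, h, nh) == \
                pytest.approx(float(nh.baseline_hazard("male", age)))

    def test_zero_beta_removes_smoking_effect(self, bundle):
        nh = dataclasses.replace(bundle.natural_history,
                                 smoking_beta={"male": 0.0, "female": 0.0})
        smoker = SmokingHistory("male", 1950, initiation_age=20)
        never = SmokingHistory("male", 1950)
        assert lung_cancer_hazard(60, smoker, nh) == \
            pytest.approx(lung_cancer_hazard(60, never, nh))

    def test_monotone_in_pack_years(self, bundle):
        nh = bundle.natural_history
        params = make_flat_cpd_params(20.0)
        light = SmokingHistory("male", 1950, initiation_age=40)   # 20 py at 60
        heavy = SmokingHistory("male", 1950, initiation_age=20)   # 40 py at 60
        assert lung_cancer_hazard(60, heavy, nh, params) > \
            lung_cancer_hazard(60, light, nh, params)

    def test_former_smoker_excess_decays(self, bundle):
        nh = bundle.natural_history
        params = make_flat_cpd_params(20.0)
        quit = SmokingHistory("male", 1950, initiation_age=20, quit_age=50)
        current = SmokingHistory("male", 1950, initiation_age=20)
        h_quit = lung_cancer_hazard(60, quit, nh, params)
        h_base = float(nh.baseline_hazard("male", 60))
        assert h_base < h_quit  # some excess remains
        # but less than a same-pack-year current smoker's
        nh_eq = dataclasses.replace(nh)
        current_30py = SmokingHistory("male", 1950, initiation_age=30)
        assert h_quit < lung_cancer_hazard(60, current_30py, nh_eq, params)


class TestSampleTumor:
    def _person(self, bundle, oc=85):
        h = SmokingHistory("male", 1950, initiation_age=20)
        return Person(id=0, sex="male", birth_year=1950, smoking=h, oc_death_age=oc)

    def test_zero_hazard_gives_no_tumor(self, bundle):
        nh = dataclasses.replace(bundle.natural_history,
                                 baseline_level={"male": 0.0, "female": 0.0})
        b = bundle.replace(natural_history=nh)
        assert sample_tumor(self._person(b), b, _rng()) is None

    def test_full_cure_means_no_lung_cancer_death(self, bundle):
        nh = dataclasses.replace(bundle.natural_history,
                                 cure_fraction=[1.0, 1.0, 1.0, 1.0],
                                 baseline_level={"male": 0.5, "female": 0.5})
        b = bundle.replace(natural_history=nh)
        rng = _rng(1)
        found = 0
        for _ in range(200):
            t = sample_tumor(self._person(b), b, rng)
            if t is not None:
                found += 1
                assert t.cured_clinical and math.isinf(t.lc_death_age_clinical)
        assert found > 0

    def test_tumor_ordering_invariant(self, bundle):
        rng = _rng(2)
        for _ in range(500):
            t = sample_tumor(self._person(bundle), bundle, rng)
            if t is not None:
                assert t.onset_age <= t.clinical_detection_age \
                    <= t.lc_death_age_clinical


class TestScreenDetectOutcome:
    def _tumor(self, stage="IV", cured=False, u_cure=0.99):
        t = Tumor(onset_age=60.0, histology="adenocarcinoma",
                  clinical_detection_age=65.0, stage_clinical=stage,
                  lc_death_age_clinical=math.inf if cured else 66.0,
                  cured_clinical=cured)
        t._u_cure = u_cure
        return t

    def test_no_stage_shift_no_benefit(self, bundle):
        """Screen stage distribution equal to clinical with uniform cure
        fractions leaves the death age unchanged."""
        nh = dataclasses.replace(bundle.natural_history, stage_shift=0.0,
                                 cure_fraction=[0.3, 0.3, 0.3, 0.3])
        t = self._tumor(u_cure=0.9)
        out = screen_detect_outcome(t, 62.0, nh, _rng())
        assert out.lc_death_age_screen == t.lc_death_age_clinical

    def test_certain_stage_one_cure(self, bundle):
        nh = dataclasses.replace(bundle.natural_history, stage_shift=1.0,
                                 stage_distribution_early=[1.0, 0.0, 0.0, 0.0],
                                 cure_fraction=[1.0, 0.3, 0.1, 0.02])
        t = self._tumor(u_cure=0.999)
        out = screen_detect_outcome(t, 62.0, nh, _rng())
        assert out.cured_screen and math.isinf(out.lc_death_age_screen)

    def test_never_earlier_death(self, bundle):
        rng = _rng(3)
        for u in np.linspace(0.01, 0.99, 25):
            t = self._tumor(u_cure=u)
            out = screen_detect_outcome(t, 61.0, bundle.natural_history, rng)
            assert out.lc_death_age_screen >= t.lc_death_age_clinical or \
                math.isinf(out.lc_death_age_screen)

    def test_outside_preclinical_window_rejected(self, bundle):
        t = self._tumor()
        with pytest.raises(ValueError):
            screen_detect_outcome(t, 66.0, bundle.natural_history, _rng())
        with pytest.raises(ValueError):
            screen_detect_outcome(t, 50.0, bundle.natural_history, _rng())

    def test_population_deaths_never_increase_under_screening(
            self, bundle, life_table):
        """Paired simulation over 10 seeds: screening can only avert deaths."""
        from lcpm.engine import apply_policy, build_cohort_state
        for seed in range(10):
            state = build_cohort_state("male", 1955, 20_000, bundle,
                                       life_table, seed=seed)
            base = apply_policy(state, None, bundle)
            scen = apply_policy(state, bundle.policies["cms"], bundle)
            assert scen.cause_lc.sum() <= base.cause_lc.sum()
            assert (scen.death_age >= base.death_age).all()


class TestIncidentalDetection:
    def test_rate_zero_never_fires(self):
        u = np.random.default_rng(0).random(1000)
        assert np.isinf(incidental_delay_years(u, 0.0)).all()

    def test_rate_one_fires_first_year(self):
        u = np.random.default_rng(0).random(1000)
        assert (incidental_delay_years(u, 1.0) == 0).all()

    def test_geometric_closed_form(self):
        """P(fire within 10 preclinical years) = 1 - 0.99^10 ~ 0.0956."""
        u = np.random.default_rng(1).random(2_000_000)
        frac = (incidental_delay_years(u, 0.01) < 10).mean()
        assert frac == pytest.approx(1 - 0.99 ** 10, rel=0.02)

    def test_scalar_api(self, bundle):
        h = SmokingHistory("male", 1950, initiation_age=20)
        p = Person(id=0, sex="male", birth_year=1950, smoking=h, oc_death_age=85)
        p.tumor = Tumor(onset_age=60.0, histology="squamous",
                        clinical_detection_age=70.0, stage_clinical="III",
                        lc_death_age_clinical=72.0, cured_clinical=False)
        nh = dataclasses.replace(bundle.natural_history, incidental_detection_rate=1.0)
        assert lcpm.incidental_detection(p, 2015, nh, _rng()) == 65.0
        nh0 = dataclasses.replace(bundle.natural_history, incidental_detection_rate=0.0)
        p.tumor.incidental_age = None
        assert lcpm.incidental_detection(p, 2015, nh0, _rng()) is None


class TestOtherCauseMortality:
    def test_certain_death_at_entry(self):
        q = np.ones((2, 3, 70))
        table = LifeTable(q=q)
        h = SmokingHistory("male", 1950)
        assert other_cause_death_age("male", h, table, _rng()) == 15

    def test_zero_rates_censor_at_cap(self):
        table = LifeTable(q=np.zeros((2, 3, 70)))
        h = SmokingHistory("male", 1950)
        assert other_cause_death_age("male", h, table, _rng()) == 85

    def test_heavier_band_stochastically_dominates(self, life_table):
        u = np.random.default_rng(4).random(100_000)
        light = sample_oc_death_ages("male", np.full(u.shape, 1), life_table, u)
        heavy = sample_oc_death_ages("male", np.full(u.shape, 2), life_table, u)
        # with shared uniforms the heavy band dies weakly earlier person by
        # person, hence its empirical CDF dominates at every age
        assert (heavy <= light).all()
        assert heavy.mean() < light.mean()
        for age in (40, 60, 80):
            assert (heavy <= age).mean() >= (light <= age).mean()

    def test_life_expectancy_matches_summation_oracle(self, life_table):
        """Discrete life expectancy equals sum over the death-age pmf."""
        q = life_table.q[0, 0]
        surv = np.cumprod(1.0 - q)
        pmf_expect = 0.0
        alive = 1.0
        for i, qi in enumerate(q):
            pmf_expect += alive * qi * i  # dies during age 15+i: i whole years
            alive *= 1.0 - qi
        pmf_expect += alive * len(q)
        assert life_table.life_expectancy("male") == pytest.approx(
            pmf_expect, abs=0.1)

    def test_csv_round_trip(self, life_table, tmp_path):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        loaded = LifeTable.from_csv(path)
        assert np.allclose(loaded.q, life_table.q)
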