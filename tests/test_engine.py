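"""Scenario engine: determinism, common random numbers, scaling, outcomes."""

import numpy as np
import pytest

import lcpm
from lcpm.engine import (
    ScenarioResult,
    compare_scenarios,
    life_years_saved,
    mortality_reduction,
    per_death,
    scale_results,
    screens_per_death_prevented,
    simulate_scenario,
)
from lcpm.parameters import SEXES, SMOKING_STATUSES

COHORTS = range(1945, 1976)  # a band of cohorts large enough to die of cancer


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, bundle, life_table):
        a = simulate_scenario(None, bundle, life_table, 3_000, seed=9,
                              cohorts=COHORTS)
        b = simulate_scenario(None, bundle, life_table, 3_000, seed=9,
                              cohorts=COHORTS)
        for field in ("deaths", "person_years", "screens", "eligible"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_compare_matches_standalone_runs(self, bundle, life_table):
        both = compare_scenarios({"baseline": None, "cms": bundle.policies["cms"]},
                                 bundle, life_table, 2_000, seed=4, cohorts=COHORTS)
        solo = simulate_scenario(bundle.policies["cms"], bundle, life_table,
                                 2_000, seed=4, cohorts=COHORTS)
        assert np.array_equal(both["cms"].deaths, solo.deaths)
        assert np.array_equal(both["cms"].screens, solo.screens)

    def test_different_seeds_differ(self, bundle, life_table):
        a = simulate_scenario(None, bundle, life_table, 3_000, seed=1,
                              cohorts=COHORTS)
        b = simulate_scenario(None, bundle, life_table, 3_000, seed=2,
                              cohorts=COHORTS)
        assert not np.array_equal(a.deaths, b.deaths)


class TestCommonRandomNumbers:
    def test_never_smokers_unaffected_by_any_policy(self, bundle, life_table):
        res = compare_scenarios(
            {"baseline": None, "cms": bundle.policies["cms"],
             "cng": bundle.policies["cng"]},
            bundle, life_table, 5_000, seed=6, cohorts=COHORTS)
        never = SMOKING_STATUSES.index("never")
        assert np.array_equal(res["baseline"].deaths[..., never],
                              res["cms"].deaths[..., never])
        assert np.array_equal(res["baseline"].deaths[..., never],
                              res["cng"].deaths[..., never])
        assert np.array_equal(res["baseline"].person_years[..., never],
                              res["cms"].person_years[..., never])

    def test_deaths_prevented_nonnegative_every_stratum(self, bundle, life_table):
        res = compare_scenarios(
            {"baseline": None, "cms": bundle.policies["cms"]},
            bundle, life_table, 5_000, seed=8, cohorts=COHORTS)
        diff = res["baseline"].deaths.sum(axis=(0, 1)) - res["cms"].deaths.sum(axis=(0, 1))
        assert (diff >= 0).all()


class TestExtensivity:
    def test_tallies_scale_with_cohort_size(self, bundle, life_table):
        small = simulate_scenario(None, bundle, life_table, 2_000, seed=5,
                                  cohorts=COHORTS)
        large = simulate_scenario(None, bundle, life_table, 8_000, seed=5,
                                  cohorts=COHORTS)
        ratio = large.total_person_years(years=(1975, 2050)) / \
            small.total_person_years(years=(1975, 2050))
        assert ratio == pytest.approx(4.0, rel=0.02)
        ratio_d = large.total_deaths(years=(1975, 2050)) / \
            small.total_deaths(years=(1975, 2050))
        assert ratio_d == pytest.approx(4.0, rel=0.15)


class _FlatProjection:
    def __init__(self, value):
        self.value = value

    def at(self, year, age, sex):
        return self.value


class TestScaling:
    def test_identity_scaling(self, bundle, life_table):
        res = simulate_scenario(None, bundle, life_table, 1_000, seed=1,
                                cohorts=range(1950, 1956))
        scaled = scale_results(res, _FlatProjection(1_000))
        assert np.allclose(scaled.deaths, res.deaths)
        assert scaled.scaled

    def test_doubling_projection_doubles_tallies(self, bundle, life_table):
        res = simulate_scenario(None, bundle, life_table, 1_000, seed=1,
                                cohorts=range(1950, 1956))
        scaled = scale_results(res, _FlatProjection(2_000))
        assert np.allclose(scaled.deaths, 2.0 * res.deaths)
        assert np.allclose(scaled.person_years, 2.0 * res.person_years)

    def test_scale_then_sum_equals_sum_then_scale(self, bundle, life_table):
        res = simulate_scenario(None, bundle, life_table, 1_000, seed=1,
                                cohorts=range(1950, 1956))
        scaled = scale_results(res, _FlatProjection(3_000))
        assert scaled.total_deaths(years=(1975, 2050)) == pytest.approx(
            3.0 * res.total_deaths(years=(1975, 2050)))


class TestConservation:
    def test_status_deaths_sum_to_total_and_cohorts_to_years(
            self, bundle, life_table):
        res = simulate_scenario(bundle.policies["cng"], bundle, life_table,
                                4_000, seed=2, cohorts=COHORTS)
        by_status = res.deaths.sum(axis=(0, 1, 2))
        assert by_status.sum() == pytest.approx(res.total_deaths(years=(1975, 2050)))
        by_cohort = res.deaths.sum(axis=(1, 2, 3))
        by_year = res.deaths.sum(axis=(0, 2, 3))
        assert by_cohort.sum() == pytest.approx(by_year.sum())

    def test_all_tallies_nonnegative(self, bundle, life_table):
        res = simulate_scenario(bundle.policies["cms"], bundle, life_table,
                                2_000, seed=2, cohorts=COHORTS)
        for field in ("deaths", "person_years", "screens", "eligible"):
            assert (getattr(res, field) >= 0).all()


def _random_totals(rng):
    return {(sex, status): float(rng.integers(100, 10_000))
            for sex in SEXES for status in SMOKING_STATUSES}


class TestOutcomeMeasures:
    def test_mortality_reduction_against_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            b_tot = _random_totals(rng)
            s_tot = _random_totals(rng)
            base = ScenarioResult.from_status_totals("baseline", b_tot)
            scen = ScenarioResult.from_status_totals("x", s_tot)
            expected = (sum(b_tot.values()) - sum(s_tot.values())) / sum(b_tot.values())
            assert mortality_reduction(base, scen) == pytest.approx(expected)
            for sex in SEXES:
                eb = sum(v for (s, _), v in b_tot.items() if s == sex)
                es = sum(v for (s, _), v in s_tot.items() if s == sex)
                assert mortality_reduction(base, scen, sex=sex) == \
                    pytest.approx((eb - es) / eb)

    def test_identical_scenarios_zero_reduction(self):
        tot = _random_totals(np.random.default_rng(0))
        base = ScenarioResult.from_status_totals("baseline", tot)
        scen = ScenarioResult.from_status_totals("x", dict(tot))
        assert mortality_reduction(base, scen) == 0.0
        assert life_years_saved(base, scen) == 0.0

    def test_zero_baseline_deaths_rejected(self):
        base = ScenarioResult.from_status_totals("baseline", {("male", "never"): 0.0})
        scen = ScenarioResult.from_status_totals("x", {("male", "never"): 0.0})
        with pytest.raises(ZeroDivisionError):
            mortality_reduction(base, scen)

    def test_life_years_per_death_printed_ratios(self):
        assert per_death(5_798_331, 721_589) == pytest.approx(8.0, abs=0.05)
        assert per_death(6_623_148, 742_563) == pytest.approx(8.9, abs=0.05)
        with pytest.raises(ZeroDivisionError):
            per_death(1000.0, 0.0)

    def test_screens_per_death_prevented(self):
        base = ScenarioResult.from_status_totals(
            "baseline", {("male", "current"): 1_010.0})
        scen = ScenarioResult.from_status_totals(
            "x", {("male", "current"): 1_000.0}, screens={"male": 1_000.0})
        assert screens_per_death_prevented(scen, base) == pytest.approx(100.0)
        with pytest.raises(ZeroDivisionError):
            screens_per_death_prevented(base, base)

    def test_csv_round_trip_layout(self, bundle, life_table, tmp_path):
        res = simulate_scenario(None, bundle, life_table, 500, seed=1,
                                cohorts=range(1950, 1953))
        path = tmp_path / "res.csv"
        res.save_csv(path, seed=1)
        text = path.read_text().splitlines()
        assert text[0].startswith("# policy=baseline")
        assert "seed=1" in text[0]
        assert text[1] == ("year,sex,smoking_status,lc_deaths,person_years,"
                           "screens,eligible")
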