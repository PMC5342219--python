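import time

import pytest

import lcpm
from lcpm import calibration, engine, synthetic


@pytest.fixture(scope="session")
def bundle():
    return lcpm.default_parameters()


@pytest.fixture(scope="session")
def life_table(bundle):
    return synthetic.generate_life_tables(bundle.other_cause)


@pytest.fixture(scope="session")
def projection(bundle, life_table):
    return synthetic.generate_population_projection(
        growth_params=bundle.population, life_table=life_table)


@pytest.fixture(scope="session")
def calibrated(bundle, life_table, projection):
    """Fully calibrated bundle at reporting scale (shared across tests)."""
    fitted, reports = calibration.calibrate(
        bundle, life_table, projection, seed=1,
        n_mortality=50_000, n_nlst=100_000)
    return fitted, reports


@pytest.fixture(scope="session")
def policy_comparison(calibrated, life_table, projection):
    """Baseline + CMS + CNG at test scale over all cohorts, scaled, timed."""
    fitted, _ = calibrated
    t0 = time.perf_counter()
    results = engine.compare_scenarios(
        {"baseline": None, "cms": fitted.policies["cms"],
         "cng": fitted.policies["cng"]},
        fitted, life_table, n_per_cohort=20_000, seed=1)
    elapsed = time.perf_counter() - t0
    scaled = {k: engine.scale_results(v, projection) for k, v in results.items()}
    return scaled, results, elapsed


def make_flat_cpd_params(cpd: float = 20.0) -> "lcpm.parameters.SmokingParameters":
    """Smoking parameters with constant cigarettes/day for analytic checks."""
    from lcpm.parameters import SmokingParameters

    return SmokingParameters(
        cpd_age_profile=[[15, cpd], [84, cpd]],
        cpd_year_trend=[[1900, 1.0], [2100, 1.0]],
        cpd_reference_year=2006,
        cpd_sex_anchor_pairs={"1998": [1.0, 1.0], "2003": [1.0, 1.0]},
    )
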