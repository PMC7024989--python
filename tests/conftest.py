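import numpy as np
import pandas as pd
import pytest

from phcguide.catalog import CauseGroup, Intervention, Platform
from phcguide.reporting import RunConfig, run_pipeline
from phcguide.synthetic_data import AGE_GROUPS, SEXES, YEARS, CountryProfile, generate_catalog


def make_country(
    country_id="T001",
    income_group="low",
    maturity="hs1",
    population_total=1_000_000.0,
    coverage=0.3,
    n_interventions=3,
    unit_price_index=1.0,
    che_history=None,
    gdp_per_capita=1000.0,
    mortality_rows=None,
    workforce_density=None,
    current_phc_exp_per_capita=25.0,
) -> CountryProfile:
    """Hand-set country profile with uniform population across ages."""
    rows = []
    per_cell = population_total / (len(AGE_GROUPS) * len(SEXES))
    for year in YEARS:
        for a in AGE_GROUPS:
            for s in SEXES:
                rows.append((year, a, s, per_cell))
    population = pd.DataFrame(rows, columns=["year", "age_group", "sex", "population"])

    if che_history is None:
        che_history = pd.Series([5.0] * 5, index=range(2015, 2020))
    if mortality_rows is None:
        mortality_rows = [(a, s, "other", 0.005) for a in AGE_GROUPS for s in SEXES]
    mortality = pd.DataFrame(mortality_rows, columns=["age_group", "sex", "cause", "rate"])

    ids = [f"I{i + 1:03d}" for i in range(n_interventions)]
    cov = coverage if np.ndim(coverage) else [coverage] * n_interventions

    return CountryProfile(
        country_id=country_id,
        income_group=income_group,
        maturity=maturity,
        population=population,
        gdp_per_capita=pd.Series([gdp_per_capita] * len(YEARS), index=YEARS),
        che_pct_gdp=che_history,
        current_phc_exp_per_capita=current_phc_exp_per_capita,
        workforce_density=workforce_density or {"doctor": 0.5, "nurse_midwife": 1.5, "other": 0.5},
        baseline_visits_per_capita=1.5,
        baseline_coverage=pd.Series(list(cov), index=ids),
        mortality_rate=mortality,
        unit_price_index=unit_price_index,
    )


def make_intervention(
    intervention_id="I001",
    tier="m1",
    target_pop_fraction=1.0,
    in_need_fraction=0.1,
    units_per_case=2.0,
    commodity_price=3.0,
    visits_per_case=1.0,
    minutes_per_visit=20.0,
    capital_share=0.0,
    effectiveness=0.5,
    cause_group=CauseGroup.OTHER,
) -> Intervention:
    return Intervention(
        intervention_id=intervention_id,
        name=f"test {intervention_id}",
        platform=Platform.FIRST_LEVEL_CLINICAL,
        in_m1=tier == "m1",
        in_m2=tier in ("m1", "m2"),
        in_m3=tier in ("m1", "m2", "m3"),
        target_pop_fraction=target_pop_fraction,
        in_need_fraction=in_need_fraction,
        units_per_case=units_per_case,
        commodity_price=commodity_price,
        visits_per_case=visits_per_case,
        minutes_per_visit=minutes_per_visit,
        capital_share=capital_share,
        effectiveness=effectiveness,
        cause_group=cause_group,
    )


@pytest.fixture(scope="session")
def default_catalog():
    return generate_catalog(seed=0)


@pytest.fixture(scope="session")
def full_bundle():
    """Full-scale 67-country, 188-intervention, 3-measure, 3-scenario run."""
    import time

    t0 = time.perf_counter()
    bundle = run_pipeline(RunConfig(seed=7))
    bundle["elapsed_seconds"] = time.perf_counter() - t0
    return bundle


@pytest.fixture(scope="session")
def small_bundle():
    return run_pipeline(RunConfig(seed=3, n_countries=5, n_interventions=24))
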