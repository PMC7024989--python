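"""Health-expenditure scenarios and PHC funding gaps.

Three scenarios for current health expenditure (CHE) as % of GDP over
2020-2030: business as usual follows each country's historical linear
trend; the progress scenario reaches a 1 percentage-point increase
over the 2019 level by 2030; the ambitious scenario reaches 2 points.
Incremental funds are measured against the 2019 per-capita expenditure
level; the PHC funding gap in a year is the positive excess of
incremental PHC cost over the (allocatable share of) incremental
funds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costing import CostResult
from .synthetic_data import CountryProfile

__all__ = [
    "SCENARIOS",
    "FinancingProjection",
    "project_che",
    "funding_gap",
    "count_gap_countries",
]

SCENARIOS = ("bau", "progress1", "ambitious2")
PROJECTION_YEARS = list(range(2020, 2031))
_CHE_BOUNDS = (1.0, 25.0)
_SCENARIO_INCREMENT = {"progress1": 1.0, "ambitious2": 2.0}


@dataclass
class FinancingProjection:
    country_id: str
    scenario: str
    che_pct_gdp_by_year: pd.Series  # index 2020-2030
    che_per_capita_by_year: pd.Series  # US$2014
    incremental_funds_by_year: pd.Series  # US$2014, vs 2019 expenditure level


def project_che(country: CountryProfile, scenario: str) -> FinancingProjection:
    """Project CHE%GDP for 2020-2030 under one scenario.

    Business as usual extrapolates the OLS linear trend of the
    historical series (clamped to [1, 25] % of GDP); the progress and
    ambitious scenarios interpolate linearly from the 2019 level to +1
    or +2 percentage points in 2030.  Per-capita values multiply by
    GDP per capita.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    hist = country.che_pct_gdp.dropna().sort_index()
    years = np.array(PROJECTION_YEARS, dtype=float)
    level_2019 = float(hist.iloc[-1])

    trend_pct = None
    if len(hist) >= 3:
        slope, intercept = np.polyfit(hist.index.to_numpy(dtype=float), hist.to_numpy(), 1)
        trend_pct = intercept + slope * years
    if scenario == "bau":
        if trend_pct is None:
            raise ValueError("business-as-usual trend needs >=3 historical points")
        pct = trend_pct
    else:
        inc = _SCENARIO_INCREMENT[scenario]
        frac = (years - 2019.0) / (2030.0 - 2019.0)
        pct = level_2019 + inc * frac
        if trend_pct is not None:
            # A scenario is an *increase*: countries already trending above
            # the target path keep their trend rather than cutting back.
            pct = np.maximum(pct, trend_pct)
    pct = np.clip(pct, *_CHE_BOUNDS)
    pct_s = pd.Series(pct, index=PROJECTION_YEARS, name="che_pct_gdp")

    gdp_pc = country.gdp_per_capita.reindex(PROJECTION_YEARS)
    che_pc = pct_s / 100.0 * gdp_pc
    che_pc_2019 = level_2019 / 100.0 * float(country.gdp_per_capita[2019])
    pops = pd.Series(
        {y: country.total_population(y) for y in PROJECTION_YEARS}, name="population"
    )
    incremental = ((che_pc - che_pc_2019) * pops).clip(lower=0.0)
    return FinancingProjection(
        country_id=country.country_id,
        scenario=scenario,
        che_pct_gdp_by_year=pct_s,
        che_per_capita_by_year=che_pc,
        incremental_funds_by_year=incremental,
    )


def _incremental_phc_cost(costs: CostResult, country_id: str, year: int) -> float:
    df = costs.line_items
    m = (df["country_id"] == country_id) & (df["year"] == year)
    return float(df.loc[m, "amount"].sum())


def funding_gap(
    projection: FinancingProjection,
    phc_cost: CostResult,
    phc_allocation: float,
    year: int,
) -> float:
    """max(0, incremental PHC cost − allocatable incremental funds)."""
    if not 0.0 < phc_allocation <= 1.0:
        raise ValueError("phc_allocation must be in (0, 1]")
    cost = _incremental_phc_cost(phc_cost, projection.country_id, year)
    funds = float(projection.incremental_funds_by_year.get(year, 0.0))
    return max(0.0, cost - phc_allocation * funds)


def count_gap_countries(
    projections: list[FinancingProjection],
    costs: CostResult,
    year: int,
    phc_allocation: float = 1.0,
) -> int:
    """Number of countries with a positive PHC funding gap in a year.

    With nested scenarios the count is non-increasing from business as
    usual through the progress and ambitious scenarios.
    """
    scenarios = {p.scenario for p in projections}
    if len(scenarios) > 1:
        raise ValueError(f"projections mix scenarios: {sorted(scenarios)}")
    return sum(
        1 for p in projections if funding_gap(p, costs, phc_allocation, year) > 0.0
    )
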