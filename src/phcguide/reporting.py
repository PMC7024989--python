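"""Investment guide posts, aggregation and the end-to-end pipeline.

Guide posts summarise, per country group (income group, maturity
category, or all countries), the additional PHC cost (total, annual,
per capita; capital+recurrent and recurrent-only), the total
recurrent per-capita cost in 2030 (current PHC expenditure plus the
additional amount — an exact accounting identity), workforce
densities, outpatient visits, deaths averted and life-expectancy
gains.  All per-capita numbers are population weighted.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import costing, financing, impact as impact_mod
from .catalog import MEASURES, MeasureSpec
from .costing import CostResult, ReferenceParams, cost_country
from .financing import count_gap_countries, funding_gap, project_che
from .impact import impact_country
from .synthetic_data import (
    GeneratorConfig,
    generate_catalog,
    generate_countries,
    write_profiles,
)

__all__ = [
    "GuidePostReport",
    "RunConfig",
    "weighted_mean",
    "guidepost_total",
    "deflate",
    "proportion_of_reference",
    "guidepost_report",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ANALYSIS_YEARS = costing.ANALYSIS_YEARS
_N_YEARS = len(ANALYSIS_YEARS)


# ---------------------------------------------------------------------------
# Elemental operations
# ---------------------------------------------------------------------------

def weighted_mean(values, weights) -> float:
    """Population-weighted mean; always lies within [min(v), max(v)]."""
    v = np.asarray(list(values), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if v.size == 0 or w.size == 0:
        raise ValueError("weighted_mean of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return float(np.sum(v * w) / np.sum(w))


def guidepost_total(current_per_capita: float, additional_per_capita: float) -> float:
    """Total PHC cost per capita: current expenditure plus the additional need."""
    if current_per_capita < 0 or additional_per_capita < 0:
        raise ValueError("per-capita amounts must be non-negative")
    return current_per_capita + additional_per_capita


def deflate(amount: float, deflator: float) -> float:
    """Convert an amount to 2014 US$ with a country price deflator."""
    if deflator <= 0:
        raise ValueError("deflator must be positive")
    return amount / deflator


def proportion_of_reference(value: float, reference: float) -> int:
    """100·value/reference as an integer percent, rounded half-up."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    pct = Decimal(100.0 * value / reference)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Guide-post assembly
# ---------------------------------------------------------------------------

@dataclass
class GuidePostReport:
    """One Table-3-style row of investment guide posts for a country group."""

    group: str
    measure_id: str
    n_countries: int
    additional_cost_total: float  # sum 2020-30, capital + recurrent
    additional_cost_annual: float
    additional_cost_annual_recurrent: float
    additional_per_capita: float  # annual, capital + recurrent
    additional_per_capita_recurrent: float
    current_phc_per_capita: float
    total_recurrent_per_capita_2030: float
    workers_per_1000_current: float
    workers_per_1000_2030: float
    visits_per_capita_2030: float
    visits_per_capita_incremental: float
    deaths_averted_total: float
    le_gain_years: float


def _per_country_summaries(
    profiles,
    ledgers: dict[str, CostResult],
    workforce: pd.DataFrame,
    visits: pd.DataFrame,
    impacts: dict[tuple[str, str], impact_mod.ImpactResult],
    measure_id: str,
    weight_year: int,
) -> pd.DataFrame:
    rows = []
    led = ledgers[measure_id].line_items
    for p in profiles:
        sub = led[led["country_id"] == p.country_id]
        total = sub["amount"].sum()
        recurrent = sub.loc[sub["cost_type"] == "recurrent", "amount"].sum()
        pop_w = p.total_population(weight_year)
        mean_pop = np.mean([p.total_population(y) for y in ANALYSIS_YEARS])
        wf = workforce[
            (workforce["country_id"] == p.country_id)
            & (workforce["measure_id"] == measure_id)
            & (workforce["year"] == 2030)
        ]
        vi = visits[
            (visits["country_id"] == p.country_id)
            & (visits["measure_id"] == measure_id)
            & (visits["year"] == 2030)
        ]
        imp = impacts[(p.country_id, measure_id)]
        rows.append(
            {
                "country_id": p.country_id,
                "income_group": p.income_group,
                "maturity": p.maturity,
                "weight_population": pop_w,
                "additional_cost_total": total,
                "additional_cost_annual": total / _N_YEARS,
                "additional_cost_annual_recurrent": recurrent / _N_YEARS,
                "additional_per_capita": total / _N_YEARS / mean_pop,
                "additional_per_capita_recurrent": recurrent / _N_YEARS / mean_pop,
                "current_phc_per_capita": p.current_phc_exp_per_capita,
                "workers_per_1000_current": sum(p.workforce_density.values()),
                "workers_per_1000_2030": float(wf["workers_per_1000_needed"].iloc[0]),
                "visits_per_capita_2030": float(vi["visits_per_capita_total"].iloc[0]),
                "visits_per_capita_incremental": float(
                    vi["visits_per_capita_incremental"].iloc[0]
                ),
                "deaths_averted_total": imp.total_deaths_averted,
                "le_gain_years": imp.le_gain_vs_2015,
            }
        )
    return pd.DataFrame(rows)


def guidepost_report(per_country: pd.DataFrame, measure_id: str) -> list[GuidePostReport]:
    """Aggregate per-country summaries into group guide posts.

    Emitted per income group, per maturity category (the eight-group
    presentation) and for all countries; per-capita values are
    population-weighted means and the 2030 total recurrent per-capita
    cost is the exact sum of current plus additional.
    """
    groups: list[tuple[str, pd.DataFrame]] = [("all", per_country)]
    for ig, sub in per_country.groupby("income_group"):
        groups.append((f"income:{ig}", sub))
    for mat, sub in per_country.groupby("maturity"):
        groups.append((f"maturity:{mat}", sub))

    out = []
    for name, sub in groups:
        w = sub["weight_population"]
        pc_add = weighted_mean(sub["additional_per_capita"], w)
        pc_add_rec = weighted_mean(sub["additional_per_capita_recurrent"], w)
        pc_cur = weighted_mean(sub["current_phc_per_capita"], w)
        out.append(
            GuidePostReport(
                group=name,
                measure_id=measure_id,
                n_countries=len(sub),
                additional_cost_total=float(sub["additional_cost_total"].sum()),
                additional_cost_annual=float(sub["additional_cost_annual"].sum()),
                additional_cost_annual_recurrent=float(
                    sub["additional_cost_annual_recurrent"].sum()
                ),
                additional_per_capita=pc_add,
                additional_per_capita_recurrent=pc_add_rec,
                current_phc_per_capita=pc_cur,
                total_recurrent_per_capita_2030=guidepost_total(pc_cur, pc_add_rec),
                workers_per_1000_current=weighted_mean(sub["workers_per_1000_current"], w),
                workers_per_1000_2030=weighted_mean(sub["workers_per_1000_2030"], w),
                visits_per_capita_2030=weighted_mean(sub["visits_per_capita_2030"], w),
                visits_per_capita_incremental=weighted_mean(
                    sub["visits_per_capita_incremental"], w
                ),
                deaths_averted_total=float(sub["deaths_averted_total"].sum()),
                le_gain_years=weighted_mean(sub["le_gain_years"], w),
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    seed: int = 0
    n_countries: int = 67
    n_interventions: int = 188
    measures: tuple[str, ...] = ("m1", "m2", "m3")
    scenarios: tuple[str, ...] = ("bau", "progress1", "ambitious2")
    phc_allocation: float = 1.0
    weight_year: int = 2020
    gap_year: int = 2030
    params: ReferenceParams = field(default_factory=ReferenceParams)
    out_dir: str | Path | None = None
    write_profile_tables: bool = False


def run_pipeline(config: RunConfig) -> dict:
    """Synthesise → cost → impact → finance → report, deterministically.

    Returns a bundle of data frames; with ``out_dir`` set, also writes
    every table as delimited text plus a run manifest.  Identical
    configs produce identical bundles.
    """
    t0 = time.perf_counter()
    gen = GeneratorConfig(
        n_countries=config.n_countries,
        seed=config.seed,
        n_interventions=config.n_interventions,
    )
    profiles = generate_countries(gen)
    catalog = generate_catalog(n_interventions=config.n_interventions, seed=config.seed)
    logger.info("simulate: %d countries, %d interventions (%.2fs)",
                len(profiles), len(catalog), time.perf_counter() - t0)

    t1 = time.perf_counter()
    ledgers: dict[str, CostResult] = {}
    wf_frames, visit_frames = [], []
    for mid in config.measures:
        measure = MEASURES[mid]
        results = []
        for p in profiles:
            cc = cost_country(p, catalog, measure, config.params)
            results.append(cc.result)
            wf_frames.append(cc.workforce)
            visit_frames.append(cc.visits)
        ledgers[mid] = CostResult.concat(results)
    workforce = pd.concat(wf_frames, ignore_index=True)
    visits = pd.concat(visit_frames, ignore_index=True)
    logger.info("cost: %d line items (%.2fs)",
                sum(len(v) for v in ledgers.values()), time.perf_counter() - t1)

    t2 = time.perf_counter()
    impacts = {
        (p.country_id, mid): impact_country(p, catalog, MEASURES[mid])
        for mid in config.measures
        for p in profiles
    }
    logger.info("impact: %d country-measures (%.2fs)", len(impacts), time.perf_counter() - t2)

    t3 = time.perf_counter()
    gap_rows = []
    primary_measure = config.measures[0]
    for scenario in config.scenarios:
        projections = [project_che(p, scenario) for p in profiles]
        for proj in projections:
            gap_rows.append(
                {
                    "country_id": proj.country_id,
                    "scenario": scenario,
                    "year": config.gap_year,
                    "gap": funding_gap(
                        proj, ledgers[primary_measure], config.phc_allocation, config.gap_year
                    ),
                }
            )
    gaps = pd.DataFrame(gap_rows)
    gap_counts = (
        gaps.assign(has_gap=gaps["gap"] > 0)
        .groupby("scenario", as_index=False)["has_gap"]
        .sum()
        .rename(columns={"has_gap": "countries_with_gap"})
    )
    logger.info("finance: %d scenarios (%.2fs)", len(config.scenarios), time.perf_counter() - t3)

    guideposts = {}
    per_country_frames = {}
    for mid in config.measures:
        per_country = _per_country_summaries(
            profiles, ledgers, workforce, visits, impacts, mid, config.weight_year
        )
        per_country_frames[mid] = per_country
        guideposts[mid] = pd.DataFrame(
            [g.__dict__ for g in guidepost_report(per_country, mid)]
        )

    impact_summary = pd.DataFrame(
        [
            {
                "country_id": cid,
                "measure_id": mid,
                "deaths_averted": res.total_deaths_averted,
                "under_five_averted": res.under_five_averted(),
                "le_2015": res.le_2015,
                "le_2030_scaleup": res.le_2030_scaleup,
                "le_gain_vs_2015": res.le_gain_vs_2015,
                "le_gain_vs_flatline": res.le_gain_vs_flatline,
                "hly_total": float(res.hly_by_area.sum()),
            }
            for (cid, mid), res in sorted(impacts.items())
        ]
    )

    bundle = {
        "profiles": profiles,
        "catalog": catalog,
        "ledgers": ledgers,
        "workforce": workforce,
        "visits": visits,
        "impacts": impacts,
        "impact_summary": impact_summary,
        "per_country": per_country_frames,
        "guideposts": guideposts,
        "gaps": gaps,
        "gap_counts": gap_counts,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ledger_all = pd.concat(
            [ledgers[m].line_items for m in config.measures], ignore_index=True
        )
        ledger_all.to_csv(out / "cost_ledger.csv", index=False)
        for mid, gp in guideposts.items():
            gp.to_csv(out / f"guideposts_{mid}.csv", index=False)
        workforce.to_csv(out / "workforce.csv", index=False)
        visits.to_csv(out / "visits.csv", index=False)
        impact_summary.to_csv(out / "impact_summary.csv", index=False)
        gaps.to_csv(out / "funding_gaps.csv", index=False)
        gap_counts.to_csv(out / "gap_counts.csv", index=False)
        manifest = {
            "seed": config.seed,
            "n_countries": config.n_countries,
            "n_interventions": config.n_interventions,
            "measures": list(config.measures),
            "scenarios": list(config.scenarios),
            "phc_allocation": config.phc_allocation,
            "weight_year": config.weight_year,
            "gap_year": config.gap_year,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if config.write_profile_tables:
            write_profiles(profiles, out / "profiles", manifest)

    logger.info("pipeline complete (%.2fs)", time.perf_counter() - t0)
    return bundle
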