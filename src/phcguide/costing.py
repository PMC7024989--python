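"""Ingredients-based PHC cost engine.

Every investment is a multiplication of annual quantities by prices:
people reached drive commodity costs, service minutes drive the
bottom-up workforce requirement, and population drives facility and
shared system costs.  Shared health-system components (infrastructure,
governance, information systems, supply chain, ...) enter each PHC
measure through the allocation shares carried on its
:class:`~phcguide.catalog.MeasureSpec`.

All costs are *incremental* to the flatline counterfactual: a
scale-up path identical to the flatline produces a zero ledger.
Capital originally scheduled in 2016-2019 is redistributed uniformly
over 2020-2030; recurrent items are reported for 2020-2030 directly.
Amounts are constant 2014 US$.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import (
    CashTransferScope,
    EmergencyScope,
    HisScope,
    Intervention,
    MeasureSpec,
    interventions_in_measure,
)
from .coverage import CoverageTrajectory, build_trajectory, flatline
from .synthetic_data import YEARS, CountryProfile

__all__ = [
    "COMPONENTS",
    "ACCOUNTING_RTOL",
    "ReferenceParams",
    "CostLineItem",
    "CostResult",
    "WorkforceRequirement",
    "CountryCosting",
    "commodity_cost",
    "fte_requirement",
    "phc_workforce_cost",
    "infrastructure_cost",
    "shared_system_cost",
    "redistribute_capital",
    "aggregate",
    "cost_country",
]

COMPONENTS = (
    "commodities",
    "workforce",
    "infrastructure",
    "equipment",
    "supply_chain",
    "cold_chain",
    "his",
    "governance",
    "financing",
    "emergency",
    "cash_transfers",
    "cross_sectoral",
    "programme_support",
)

#: Relative tolerance at which grouped totals must reproduce line-item sums.
ACCOUNTING_RTOL = 1e-6

ANALYSIS_YEARS = list(range(2020, 2031))
CAPITAL_SOURCE_YEARS = list(range(2016, 2020))

_HIS_SCOPE_FACTOR = {
    HisScope.FACILITY_ONLY: 0.60,
    HisScope.FULL_SECTOR: 1.00,
    HisScope.FULL_SECTOR_PLUS_CENSUS: 1.25,
}
_CASH_SCOPE_FACTOR = {
    CashTransferScope.NONE: 0.0,
    CashTransferScope.BIRTH_ONLY: 0.15,
    CashTransferScope.GENERAL: 1.0,
}


@dataclass(frozen=True)
class ReferenceParams:
    """Reference unit costs and norms behind the shared-system components.

    Per-capita bases are annual 2014 US$ at a unit-price index of 1;
    country price levels scale them through ``unit_price_index``.
    ``minutes_per_fte_year`` is the service time available per
    full-time worker-year; ``density_target`` is the benchmark
    health-worker density the parent workforce model is calibrated to.
    """

    salary_per_fte: float = 4200.0  # US$ per FTE-year, blended cadres
    minutes_per_fte_year: float = 99_000.0
    density_target: float = 8.8  # workers per 1000 population
    facility_capital_pc: dict[str, float] = field(
        default_factory=lambda: {"health_centre": 7.5, "district_hospital": 5.0, "provincial_hospital": 3.0}
    )
    facility_recurrent_pc: dict[str, float] = field(
        default_factory=lambda: {"health_centre": 4.5, "district_hospital": 3.0, "provincial_hospital": 2.0}
    )
    equipment_capital_pc: float = 2.5
    supply_chain_pc: float = 1.5
    cold_chain_pc: float = 0.25
    his_pc: float = 1.0
    governance_pc: float = 1.4
    financing_pc: float = 1.0
    emergency_pc: float = 0.8
    cash_transfer_pc: float = 2.0
    cross_sectoral_pc: float = 4.0
    programme_support_rate: float = 0.10
    #: Σ of per-intervention coverage gains that counts as a "full"
    #: system scale-up (half the 188-intervention package moving 1.0).
    intensity_norm: float = 94.0

    def with_overrides(self, **kwargs) -> "ReferenceParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CostLineItem:
    country_id: str
    year: int
    measure_id: str
    component: str
    cost_type: str  # capital | recurrent
    amount: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("cost amounts must be non-negative")
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.cost_type not in ("capital", "recurrent"):
            raise ValueError(f"unknown cost_type {self.cost_type!r}")


_LEDGER_COLUMNS = ["country_id", "year", "measure_id", "component", "cost_type", "amount"]


class CostResult:
    """Country-year-measure-component ledger of incremental costs."""

    def __init__(self, line_items: pd.DataFrame | list[CostLineItem] | None = None):
        if line_items is None:
            df = pd.DataFrame(columns=_LEDGER_COLUMNS)
        elif isinstance(line_items, pd.DataFrame):
            df = line_items[_LEDGER_COLUMNS].copy()
        else:
            df = pd.DataFrame([li.__dict__ for li in line_items], columns=_LEDGER_COLUMNS)
        if len(df) and (df["amount"] < 0).any():
            raise ValueError("cost amounts must be non-negative")
        self.line_items = df.reset_index(drop=True)

    def total(self) -> float:
        return float(self.line_items["amount"].sum())

    def totals(self, by: list[str] | tuple[str, ...]) -> pd.DataFrame:
        """Grouped sums; conservation to line items is exact by construction."""
        return self.line_items.groupby(list(by), as_index=False)["amount"].sum()

    @staticmethod
    def concat(results: list["CostResult"]) -> "CostResult":
        frames = [r.line_items for r in results if len(r.line_items)]
        if not frames:
            return CostResult()
        return CostResult(pd.concat(frames, ignore_index=True))

    def __len__(self) -> int:
        return len(self.line_items)


@dataclass(frozen=True)
class WorkforceRequirement:
    country_id: str
    year: int
    fte_by_cadre: dict[str, float]
    phc_share: float
    workers_per_1000: float
    visits_per_capita: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fte_by_cadre.values()):
            raise ValueError("FTE counts must be non-negative")
        if not 0.0 <= self.phc_share <= 1.0:
            raise ValueError("phc_share must lie in [0,1]")


# ---------------------------------------------------------------------------
# Elemental operations
# ---------------------------------------------------------------------------

def commodity_cost(
    country: CountryProfile,
    intervention: Intervention,
    trajectory: CoverageTrajectory,
    year: int,
    flatline_trajectory: CoverageTrajectory | None = None,
) -> float:
    """Medicines/diagnostics/supplies cost: people reached × units × price.

    With ``flatline_trajectory`` given, returns the incremental amount
    (scale-up minus counterfactual).
    """
    if not 2015 <= year <= 2030:
        raise ValueError(f"year {year} outside the projection horizon")
    if intervention.commodity_price is None or np.isnan(intervention.commodity_price):
        raise ValueError(f"missing commodity price for {intervention.intervention_id}")
    pop = country.total_population(year)

    def _amount(cov: float) -> float:
        reached = (
            pop
            * intervention.target_pop_fraction
            * intervention.in_need_fraction
            * cov
        )
        return (
            reached
            * intervention.units_per_case
            * intervention.commodity_price
            * country.unit_price_index
        )

    amount = _amount(trajectory.at(year))
    if flatline_trajectory is not None:
        amount -= _amount(flatline_trajectory.at(year))
    return amount


def fte_requirement(visit_minutes_total: float, minutes_per_fte_year: float) -> float:
    """Full-time-equivalent workers needed to deliver the service minutes."""
    if minutes_per_fte_year <= 0:
        raise ValueError("minutes_per_fte_year must be positive")
    if visit_minutes_total < 0:
        raise ValueError("service minutes must be non-negative")
    return visit_minutes_total / minutes_per_fte_year


def phc_workforce_cost(
    fte_phc: float,
    fte_all_sdg: float,
    density_target: float,
    population: float,
    salary: float,
    current_workers: float = 0.0,
) -> tuple[float, WorkforceRequirement, float]:
    """Density-calibrated PHC workforce cost from the bottom-up share.

    The bottom-up FTE ratio (PHC package over the full package) is
    applied to the density-benchmark workforce; the cost is that PHC
    workforce times the salary.  Returns (cost, requirement,
    incremental_workers) where incremental workers are floored at
    zero against the current workforce.
    """
    if density_target <= 0:
        raise ValueError("density_target must be positive")
    if fte_phc < 0 or fte_all_sdg < 0 or fte_phc > fte_all_sdg:
        raise ValueError("require 0 <= fte_phc <= fte_all_sdg")
    share = 0.0 if fte_all_sdg == 0 else fte_phc / fte_all_sdg
    workers = share * density_target * population / 1000.0
    cost = workers * salary
    incremental = max(0.0, workers - current_workers)
    req = WorkforceRequirement(
        country_id="",
        year=0,
        fte_by_cadre={"all": workers},
        phc_share=share,
        workers_per_1000=0.0 if population == 0 else workers / population * 1000.0,
        visits_per_capita=0.0,
    )
    return cost, req, incremental


def infrastructure_cost(
    facility_costs: dict[str, float], measure: MeasureSpec
) -> dict[str, float]:
    """Apply the measure's facility-level shares to infrastructure costs.

    Health centres count in full; district and provincial hospitals by
    the national-health-accounts-derived shares of the measure.
    """
    shares = {
        "health_centre": measure.health_centre_share,
        "district_hospital": measure.district_hospital_share,
        "provincial_hospital": measure.provincial_hospital_share,
    }
    out = {}
    for level, amount in facility_costs.items():
        if level not in shares:
            raise ValueError(f"unknown facility level {level!r}")
        if amount < 0:
            raise ValueError("facility costs must be non-negative")
        out[level] = amount * shares[level]
    return out


def shared_system_cost(
    component: str,
    full_amount: float,
    measure: MeasureSpec,
    commodity_ratio: float = 0.0,
) -> float:
    """Share of a full-sector system cost attributed to a PHC measure.

    Governance and financing scale by the measure shares; supply chain
    by the PHC-to-total commodity cost ratio; cold chain, emergency
    relief and post-conflict reconstruction pass through in full;
    information systems and emergency preparedness scale with the
    measure's scope switches; cash transfers with the transfer scope.
    """
    if full_amount < 0:
        raise ValueError("full_amount must be non-negative")
    if not 0.0 <= commodity_ratio <= 1.0:
        raise ValueError("commodity_ratio must lie in [0,1]")
    if component == "governance":
        return full_amount * measure.governance_share
    if component == "financing":
        return full_amount * measure.financing_share
    if component == "supply_chain":
        return full_amount * commodity_ratio
    if component in ("cold_chain", "emergency_relief", "post_conflict_reconstruction"):
        return full_amount
    if component == "his":
        return full_amount * _HIS_SCOPE_FACTOR[measure.his_scope]
    if component == "emergency":
        if measure.emergency_scope is EmergencyScope.LAB_SHARE_ONLY:
            return full_amount * measure.district_hospital_share
        return full_amount
    if component == "cash_transfers":
        return full_amount * _CASH_SCOPE_FACTOR[measure.cash_transfer_scope]
    if component == "cross_sectoral":
        return full_amount if measure.includes_cross_sectoral else 0.0
    raise ValueError(f"unknown shared component {component!r}")


def redistribute_capital(
    ledger: CostResult,
    source_years: list[int] | None = None,
    target_years: list[int] | None = None,
) -> CostResult:
    """Move capital from the source years uniformly over the target years.

    Capital originally scheduled for 2016-2019 is spread evenly across
    2020-2030; recurrent items are untouched and the capital total is
    conserved exactly.
    """
    source_years = list(source_years or CAPITAL_SOURCE_YEARS)
    target_years = list(target_years or ANALYSIS_YEARS)
    if set(source_years) & set(target_years):
        raise ValueError("source and target years must not overlap")
    df = ledger.line_items
    is_source_capital = (df["cost_type"] == "capital") & df["year"].isin(source_years)
    if not is_source_capital.any():
        return CostResult(df)
    moved = (
        df.loc[is_source_capital]
        .groupby(["country_id", "measure_id", "component"], as_index=False)["amount"]
        .sum()
    )
    spread = []
    for _, row in moved.iterrows():
        per_year = row["amount"] / len(target_years)
        for y in target_years:
            spread.append(
                {
                    "country_id": row["country_id"],
                    "year": y,
                    "measure_id": row["measure_id"],
                    "component": row["component"],
                    "cost_type": "capital",
                    "amount": per_year,
                }
            )
    out = pd.concat(
        [df.loc[~is_source_capital], pd.DataFrame(spread, columns=_LEDGER_COLUMNS)],
        ignore_index=True,
    )
    return CostResult(out)


def aggregate(results: CostResult, grouping: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Grouped cost totals (thin wrapper kept for a stable surface)."""
    return results.totals(grouping)


# ---------------------------------------------------------------------------
# Country-level engine
# ---------------------------------------------------------------------------

@dataclass
class CountryCosting:
    """Full costing output for one country under one measure."""

    result: CostResult
    workforce: pd.DataFrame  # year, phc_share, workers_per_1000_needed, incremental_workers
    visits: pd.DataFrame  # year, visits_per_capita_total, visits_per_capita_incremental


def _coverage_matrices(
    country: CountryProfile, catalog: list[Intervention]
) -> tuple[np.ndarray, np.ndarray]:
    """(scale-up, flatline) coverage matrices, interventions × years."""
    ids = [iv.intervention_id for iv in catalog]
    baselines = country.baseline_coverage.reindex(ids).fillna(0.0).to_numpy()
    cov_s = np.vstack(
        [build_trajectory(b, country.maturity).values for b in baselines]
    )
    cov_f = np.tile(baselines[:, None], (1, len(YEARS)))
    return cov_s, cov_f


def cost_country(
    country: CountryProfile,
    catalog: list[Intervention],
    measure: MeasureSpec,
    params: ReferenceParams | None = None,
    apply_redistribution: bool = True,
) -> CountryCosting:
    """Incremental ingredients-based costing of one country-measure.

    Direct intervention costs come from people reached under the
    scale-up minus the flatline; the system components scale with the
    aggregate coverage effort of the measure's package (so a zero
    scale-up yields a zero ledger) and with the measure's allocation
    shares.  Capital modelled in 2016-2019 is redistributed over
    2020-2030 unless ``apply_redistribution`` is disabled.
    """
    params = params or ReferenceParams()
    upi = country.unit_price_index
    years = np.array(YEARS)
    pop = np.array([country.total_population(int(y)) for y in years])

    cov_s, cov_f = _coverage_matrices(country, catalog)
    tpf = np.array([iv.target_pop_fraction for iv in catalog])
    inf = np.array([iv.in_need_fraction for iv in catalog])
    units = np.array([iv.units_per_case for iv in catalog])
    price = np.array([iv.commodity_price for iv in catalog])
    vpc = np.array([iv.visits_per_case for iv in catalog])
    mpv = np.array([iv.minutes_per_visit for iv in catalog])
    capsh = np.array([iv.capital_share for iv in catalog])

    reach_s = pop[None, :] * tpf[:, None] * inf[:, None] * cov_s
    reach_f = pop[None, :] * tpf[:, None] * inf[:, None] * cov_f
    comm_s = reach_s * (units * price)[:, None] * upi
    comm_f = reach_f * (units * price)[:, None] * upi
    visits_s = reach_s * vpc[:, None]
    visits_f = reach_f * vpc[:, None]
    minutes_s = visits_s * mpv[:, None]
    minutes_f = visits_f * mpv[:, None]

    member = np.array([iv.in_measure(measure.measure_id) for iv in catalog])
    yi = {int(y): k for k, y in enumerate(years)}
    a_idx = [yi[y] for y in ANALYSIS_YEARS]
    s_idx = [yi[y] for y in CAPITAL_SOURCE_YEARS]

    rows: list[dict] = []

    def add(year: int, component: str, cost_type: str, amount: float) -> None:
        if amount > 0:
            rows.append(
                {
                    "country_id": country.country_id,
                    "year": year,
                    "measure_id": measure.measure_id,
                    "component": component,
                    "cost_type": cost_type,
                    "amount": float(amount),
                }
            )

    # --- direct intervention costs (incremental people reached) ----------
    comm_incr = (comm_s - comm_f)[member]  # >= 0: scale-up >= flatline
    direct_by_year = comm_incr.sum(axis=0)
    equip_from_iv = (comm_incr * capsh[member][:, None]).sum(axis=0)
    commodities_by_year = direct_by_year - equip_from_iv
    for k in a_idx:
        add(int(years[k]), "commodities", "recurrent", commodities_by_year[k])
        add(int(years[k]), "equipment", "capital", equip_from_iv[k])
        add(
            int(years[k]),
            "programme_support",
            "recurrent",
            params.programme_support_rate * direct_by_year[k],
        )

    # --- workforce (bottom-up share applied to the density benchmark) ----
    fte_all_s = minutes_s.sum(axis=0) / params.minutes_per_fte_year
    fte_phc_s = minutes_s[member].sum(axis=0) / params.minutes_per_fte_year
    fte_phc_f = minutes_f[member].sum(axis=0) / params.minutes_per_fte_year
    with np.errstate(invalid="ignore", divide="ignore"):
        share_s = np.where(fte_all_s > 0, fte_phc_s / fte_all_s, 0.0)
        share_f = np.where(fte_all_s > 0, fte_phc_f / fte_all_s, 0.0)
    bench = params.density_target * pop / 1000.0
    workers_s = share_s * bench
    workers_f = share_f * bench
    current_density = sum(country.workforce_density.values())
    current_phc = share_s * current_density * pop / 1000.0
    incr_workers = np.maximum(0.0, workers_s - np.maximum(workers_f, current_phc))
    wf_rows = []
    for k in a_idx:
        y = int(years[k])
        add(y, "workforce", "recurrent", incr_workers[k] * params.salary_per_fte * upi)
        wf_rows.append(
            {
                "country_id": country.country_id,
                "measure_id": measure.measure_id,
                "year": y,
                "phc_share": share_s[k],
                "workers_per_1000_needed": workers_s[k] / pop[k] * 1000.0,
                "workers_per_1000_current": current_density,
                "incremental_workers": incr_workers[k],
            }
        )

    # --- outpatient-visit guide posts ------------------------------------
    vis_rows = []
    for k in a_idx:
        vis_rows.append(
            {
                "country_id": country.country_id,
                "measure_id": measure.measure_id,
                "year": int(years[k]),
                "visits_per_capita_total": visits_s[member, k].sum() / pop[k],
                "visits_per_capita_incremental": (visits_s - visits_f)[member, k].sum() / pop[k],
            }
        )

    # --- system components scaled by the measure's coverage effort -------
    dcov = (cov_s - cov_f)[member]
    intensity = dcov.sum(axis=0) / params.intensity_norm
    intensity_full = float(intensity[yi[2030]])

    levels = ("health_centre", "district_hospital", "provincial_hospital")
    for k in s_idx:  # capital, modelled in 2016-2019, redistributed below
        y = int(years[k])
        infra_cap = infrastructure_cost(
            {lv: params.facility_capital_pc[lv] * pop[k] * upi * intensity_full for lv in levels},
            measure,
        )
        add(y, "infrastructure", "capital", sum(infra_cap.values()))
        eq_share = (
            0.50 * measure.health_centre_share
            + 0.35 * measure.district_hospital_share
            + 0.15 * measure.provincial_hospital_share
        )
        add(y, "equipment", "capital", params.equipment_capital_pc * pop[k] * upi * intensity_full * eq_share)

    births = {y: country.births(y) for y in ANALYSIS_YEARS}
    total_births_pc = {y: births[y] / pop[yi[y]] for y in ANALYSIS_YEARS}
    for k in a_idx:
        y = int(years[k])
        it = float(intensity[k])
        infra_rec = infrastructure_cost(
            {lv: params.facility_recurrent_pc[lv] * pop[k] * upi * it for lv in levels}, measure
        )
        add(y, "infrastructure", "recurrent", sum(infra_rec.values()))

        comm_ratio_num = comm_s[member, k].sum()
        comm_ratio_den = comm_s[:, k].sum()
        ratio = 0.0 if comm_ratio_den == 0 else min(1.0, comm_ratio_num / comm_ratio_den)
        add(
            y,
            "supply_chain",
            "recurrent",
            shared_system_cost("supply_chain", params.supply_chain_pc * pop[k] * upi * it, measure, ratio),
        )
        add(y, "cold_chain", "recurrent", shared_system_cost("cold_chain", params.cold_chain_pc * pop[k] * upi * it, measure))
        add(y, "his", "recurrent", shared_system_cost("his", params.his_pc * pop[k] * upi * it, measure))
        add(y, "governance", "recurrent", shared_system_cost("governance", params.governance_pc * pop[k] * upi * it, measure))
        add(y, "financing", "recurrent", shared_system_cost("financing", params.financing_pc * pop[k] * upi * it, measure))
        add(y, "emergency", "recurrent", shared_system_cost("emergency", params.emergency_pc * pop[k] * upi * it, measure))
        # Cash transfers: the birth-linked scope is the births' share of a
        # general per-capita transfer programme.
        cash_full = params.cash_transfer_pc * pop[k] * upi * it
        if measure.cash_transfer_scope is CashTransferScope.BIRTH_ONLY:
            cash = cash_full * _CASH_SCOPE_FACTOR[CashTransferScope.BIRTH_ONLY] * min(
                1.0, total_births_pc[y] / 0.03
            )
        else:
            cash = shared_system_cost("cash_transfers", cash_full, measure)
        add(y, "cash_transfers", "recurrent", cash)
        add(
            y,
            "cross_sectoral",
            "recurrent",
            shared_system_cost("cross_sectoral", params.cross_sectoral_pc * pop[k] * upi * it, measure),
        )

    result = CostResult(pd.DataFrame(rows, columns=_LEDGER_COLUMNS))
    if apply_redistribution:
        result = redistribute_capital(result)
    return CountryCosting(
        result=result,
        workforce=pd.DataFrame(wf_rows),
        visits=pd.DataFrame(vis_rows),
    )
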