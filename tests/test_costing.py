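"""Ingredients-cost engine: elemental operations and engine invariants."""

import numpy as np
import pandas as pd
import pytest

from phcguide.catalog import MEASURES
from phcguide.costing import (
    ANALYSIS_YEARS,
    CostLineItem,
    CostResult,
    ReferenceParams,
    aggregate,
    commodity_cost,
    cost_country,
    fte_requirement,
    infrastructure_cost,
    phc_workforce_cost,
    redistribute_capital,
    shared_system_cost,
)
from phcguide.coverage import build_trajectory, flatline
from conftest import make_country, make_intervention


# ---------------------------------------------------------------------------
# Elemental operations
# ---------------------------------------------------------------------------

class TestCommodityCost:
    def test_quantities_times_prices(self):
        country = make_country(population_total=1_000_000, coverage=0.6, n_interventions=1)
        iv = make_intervention(target_pop_fraction=1.0, in_need_fraction=0.1,
                               units_per_case=2.0, commodity_price=3.0)
        traj = flatline(0.6)
        assert commodity_cost(country, iv, traj, 2025) == pytest.approx(360_000.0)

    def test_incremental_subtracts_flatline(self):
        country = make_country(population_total=1_000_000, n_interventions=1)
        iv = make_intervention()
        amount = commodity_cost(country, iv, flatline(0.6), 2025, flatline(0.4))
        assert amount == pytest.approx(120_000.0)

    def test_zero_increment_identity(self):
        country = make_country(n_interventions=1)
        iv = make_intervention()
        assert commodity_cost(country, iv, flatline(0.5), 2025, flatline(0.5)) == 0.0

    def test_price_index_scales(self):
        c1 = make_country(unit_price_index=1.0, n_interventions=1)
        c2 = make_country(unit_price_index=2.0, n_interventions=1)
        iv = make_intervention()
        assert commodity_cost(c2, iv, flatline(0.5), 2025) == pytest.approx(
            2 * commodity_cost(c1, iv, flatline(0.5), 2025)
        )


class TestWorkforce:
    def test_fte_from_service_minutes(self):
        assert fte_requirement(100_000 * 19.8, 99_000) == pytest.approx(20.0)
        assert fte_requirement(0.0, 99_000) == 0.0
        assert fte_requirement(2 * 100_000 * 19.8, 99_000) == pytest.approx(40.0)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            fte_requirement(1000.0, 0.0)

    def test_share_applied_to_density_benchmark(self):
        cost, req, incr = phc_workforce_cost(
            fte_phc=20, fte_all_sdg=50, density_target=6.0,
            population=1_000_000, salary=5_000.0,
        )
        assert req.phc_share == pytest.approx(0.4)
        assert req.fte_by_cadre["all"] == pytest.approx(2_400.0)
        assert cost == pytest.approx(12_000_000.0)

    def test_full_share_and_zero_floor(self):
        _, req, _ = phc_workforce_cost(10, 10, 6.0, 1e6, 1.0)
        assert req.phc_share == 1.0
        _, _, incr = phc_workforce_cost(10, 20, 6.0, 1e6, 1.0, current_workers=1e5)
        assert incr == 0.0
        _, req0, _ = phc_workforce_cost(0, 0, 6.0, 1e6, 1.0)
        assert req0.phc_share == 0.0

    def test_phc_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            phc_workforce_cost(30, 20, 6.0, 1e6, 1.0)


class TestInfrastructureShares:
    @pytest.mark.parametrize(
        "level,m1_expected,m2_expected",
        [
            ("district_hospital", 33.0, 81.0),
            ("provincial_hospital", 3.0, 27.0),
            ("health_centre", 100.0, 100.0),
        ],
    )
    def test_table_shares(self, level, m1_expected, m2_expected):
        out1 = infrastructure_cost({level: 100.0}, MEASURES["m1"])
        out2 = infrastructure_cost({level: 100.0}, MEASURES["m2"])
        assert out1[level] == pytest.approx(m1_expected)
        assert out2[level] == pytest.approx(m2_expected)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            infrastructure_cost({"clinic": 10.0}, MEASURES["m1"])


class TestSharedSystemCost:
    def test_governance_partial_then_full(self):
        assert shared_system_cost("governance", 50.0, MEASURES["m1"]) == pytest.approx(40.0)
        assert shared_system_cost("governance", 50.0, MEASURES["m2"]) == pytest.approx(50.0)

    def test_supply_chain_commodity_ratio(self):
        assert shared_system_cost("supply_chain", 200.0, MEASURES["m1"], 0.35) == pytest.approx(70.0)

    def test_cold_chain_passes_through_fully(self):
        for m in MEASURES.values():
            assert shared_system_cost("cold_chain", 10.0, m) == 10.0

    def test_emergency_lab_share_vs_full(self):
        assert shared_system_cost("emergency", 100.0, MEASURES["m1"]) == pytest.approx(33.0)
        assert shared_system_cost("emergency", 100.0, MEASURES["m2"]) == 100.0

    def test_cross_sectoral_only_in_m3(self):
        assert shared_system_cost("cross_sectoral", 10.0, MEASURES["m2"]) == 0.0
        assert shared_system_cost("cross_sectoral", 10.0, MEASURES["m3"]) == 10.0

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            shared_system_cost("catering", 10.0, MEASURES["m1"])


class TestRedistribution:
    @staticmethod
    def _capital_ledger(amount_per_year=11.0):
        items = [
            CostLineItem("C1", y, "m1", "infrastructure", "capital", amount_per_year)
            for y in range(2016, 2020)
        ]
        items.append(CostLineItem("C1", 2025, "m1", "commodities", "recurrent", 7.0))
        return CostResult(items)

    def test_uniform_spread_and_zeroed_source(self):
        out = redistribute_capital(self._capital_ledger())  # $44 over 4 years
        df = out.line_items
        cap = df[df["cost_type"] == "capital"]
        assert sorted(cap["year"]) == ANALYSIS_YEARS
        assert np.allclose(cap["amount"], 4.0)
        assert not ((df["year"] < 2020) & (df["cost_type"] == "capital")).any()

    def test_capital_total_conserved_and_recurrent_untouched(self):
        before = self._capital_ledger()
        after = redistribute_capital(before)
        for ct in ("capital", "recurrent"):
            b = before.line_items.query("cost_type == @ct")["amount"].sum()
            a = after.line_items.query("cost_type == @ct")["amount"].sum()
            assert a == pytest.approx(b, rel=1e-12)

    def test_no_source_capital_is_identity(self):
        ledger = CostResult([CostLineItem("C1", 2025, "m1", "commodities", "recurrent", 7.0)])
        out = redistribute_capital(ledger)
        pd.testing.assert_frame_equal(out.line_items, ledger.line_items)

    def test_overlapping_years_rejected(self):
        with pytest.raises(ValueError):
            redistribute_capital(self._capital_ledger(), [2019, 2020], [2020, 2021])


class TestAggregate:
    def test_group_totals(self):
        items = [
            CostLineItem(c, 2025, "m1", "commodities", "recurrent", amt * 1e9)
            for c, amt in [("low", 30.0), ("lmic", 77.0), ("umic", 72.0)]
        ]
        res = CostResult(items)
        assert res.total() == pytest.approx(179e9)
        by_country = aggregate(res, ["country_id"])
        assert set(by_country["amount"]) == {30e9, 77e9, 72e9}

    def test_single_item(self):
        res = CostResult([CostLineItem("C1", 2020, "m1", "his", "recurrent", 5.0)])
        assert res.total() == 5.0

    def test_negative_amounts_rejected(self):
        with pytest.raises(ValueError):
            CostLineItem("C1", 2020, "m1", "his", "recurrent", -1.0)


# ---------------------------------------------------------------------------
# Engine invariants
# ---------------------------------------------------------------------------

def _two_tier_catalog():
    return [
        make_intervention("I001", tier="m1", capital_share=0.2),
        make_intervention("I002", tier="m2", commodity_price=1.0),
        make_intervention("I003", tier="m3", units_per_case=1.0),
    ]


def test_measure_cost_monotonicity_per_year():
    country = make_country(coverage=0.3, n_interventions=3)
    catalog = _two_tier_catalog()
    totals = {}
    for mid in ("m1", "m2", "m3"):
        cc = cost_country(country, catalog, MEASURES[mid])
        totals[mid] = cc.result.totals(["year"]).set_index("year")["amount"]
    for y in ANALYSIS_YEARS:
        assert totals["m1"].get(y, 0) <= totals["m2"].get(y, 0) + 1e-9
        assert totals["m2"].get(y, 0) <= totals["m3"].get(y, 0) + 1e-9


def test_zero_scaleup_produces_empty_ledger():
    # baseline above every maturity target -> no coverage change anywhere
    country = make_country(coverage=1.0, maturity="hs3", n_interventions=3)
    cc = cost_country(country, _two_tier_catalog(), MEASURES["m3"])
    assert cc.result.total() == 0.0


def test_price_homogeneity_of_full_ledger():
    c1 = make_country(coverage=0.3, unit_price_index=1.0, n_interventions=3)
    c2 = make_country(coverage=0.3, unit_price_index=2.0, n_interventions=3)
    catalog = _two_tier_catalog()
    t1 = cost_country(c1, catalog, MEASURES["m2"]).result.total()
    t2 = cost_country(c2, catalog, MEASURES["m2"]).result.total()
    assert t2 == pytest.approx(2 * t1, rel=1e-9)


def test_component_totals_sum_to_grand_total():
    country = make_country(coverage=0.3, n_interventions=3)
    cc = cost_country(country, _two_tier_catalog(), MEASURES["m3"])
    by_comp = cc.result.totals(["component"])["amount"].sum()
    assert by_comp == pytest.approx(cc.result.total(), rel=1e-12)


def test_spreadsheet_oracle_parameter_recovery():
    """Hand-computed spreadsheet oracle on 5 hand-set countries (<0.1%).

    System bases are hand-set so that every ledger component can be
    recomputed with plain spreadsheet arithmetic from the posted
    formulas; the engine must match per country to better than 0.1%.
    """
    params = ReferenceParams(
        salary_per_fte=5_000.0,
        minutes_per_fte_year=99_000.0,
        density_target=6.0,
        facility_capital_pc={"health_centre": 2.0, "district_hospital": 1.0, "provincial_hospital": 0.5},
        facility_recurrent_pc={"health_centre": 1.0, "district_hospital": 0.5, "provincial_hospital": 0.25},
        equipment_capital_pc=0.0,
        supply_chain_pc=0.0,
        cold_chain_pc=0.0,
        his_pc=0.0,
        governance_pc=2.0,
        financing_pc=0.0,
        emergency_pc=0.0,
        cash_transfer_pc=0.0,
        cross_sectoral_pc=0.0,
        programme_support_rate=0.10,
        intensity_norm=1.0,
    )
    measure = MEASURES["m1"]
    catalog = [
        make_intervention("I001", tier="m1", target_pop_fraction=1.0, in_need_fraction=0.1,
                          units_per_case=2.0, commodity_price=3.0, visits_per_case=1.0,
                          minutes_per_visit=19.8, capital_share=0.0),
        make_intervention("I002", tier="m2", target_pop_fraction=0.5, in_need_fraction=0.2,
                          units_per_case=1.0, commodity_price=4.0, visits_per_case=2.0,
                          minutes_per_visit=10.0, capital_share=0.0),
    ]
    specs = [  # (population, baseline coverage, price index)
        (1_000_000, 0.20, 1.0),
        (2_000_000, 0.40, 0.8),
        (500_000, 0.10, 1.2),
        (3_000_000, 0.55, 1.0),
        (750_000, 0.35, 0.9),
    ]
    target = 0.85  # hs1
    current_density = 2.5  # from make_country defaults

    for k, (pop, base, upi) in enumerate(specs):
        country = make_country(
            country_id=f"S{k}", maturity="hs1", population_total=pop,
            coverage=base, n_interventions=2, unit_price_index=upi,
        )
        engine_pc = cost_country(country, catalog, measure, params).result.total() / pop

        # --- independent spreadsheet arithmetic -------------------------
        oracle = 0.0
        cov = {y: base + max(0, y - 2019) / 11 * (target - base) for y in range(2015, 2031)}
        for y in range(2020, 2031):
            dcov = cov[y] - base
            # direct: only I001 is in m1
            direct = pop * 1.0 * 0.1 * dcov * 2.0 * 3.0 * upi
            oracle += direct * 1.10  # commodities + 10% programme support
            # workforce: minutes under scale-up vs flatline, same denominator
            min_s1 = pop * 0.1 * cov[y] * 1.0 * 19.8
            min_f1 = pop * 0.1 * base * 1.0 * 19.8
            min_s2 = pop * 0.5 * 0.2 * cov[y] * 2.0 * 10.0
            fte_all = (min_s1 + min_s2) / 99_000.0
            w_s = (min_s1 / 99_000.0) / fte_all * 6.0 * pop / 1000
            w_f = (min_f1 / 99_000.0) / fte_all * 6.0 * pop / 1000
            cur = (min_s1 / 99_000.0) / fte_all * current_density * pop / 1000
            oracle += max(0.0, w_s - max(w_f, cur)) * 5_000.0 * upi
            # recurrent infrastructure and governance scale with Δcoverage
            infra = (1.0 * 1.0 + 0.5 * 0.33 + 0.25 * 0.03) * pop * upi * dcov
            oracle += infra + 2.0 * pop * upi * dcov * 0.80
        # capital modelled 2016-19 at terminal intensity, conserved by spread
        dcov30 = cov[2030] - base
        oracle += 4 * (2.0 * 1.0 + 1.0 * 0.33 + 0.5 * 0.03) * pop * upi * dcov30

        assert engine_pc == pytest.approx(oracle / pop, rel=1e-3)
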