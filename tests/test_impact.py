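"""Deaths averted, life tables, LE gains and healthy life-years."""

import numpy as np
import pandas as pd
import pytest

from phcguide.catalog import MEASURES, CauseGroup
from phcguide.coverage import CoverageTrajectory
from phcguide.impact import (
    averted_death_life_years,
    build_life_table,
    deaths_averted,
    default_ax,
    external_cause_adjustment,
    hly_gained,
    impact_country,
    le_gain,
)
from phcguide.synthetic_data import AGE_GROUPS, SEXES, YEARS
from conftest import make_country, make_intervention


def _const(v):
    return CoverageTrajectory(np.full(len(YEARS), v))


def _country_with_cause_deaths(cause="other", total_deaths=10_000.0, pop=1_000_000.0):
    # uniform population; rate set so the cause kills `total_deaths`/year
    per_cell = pop / (len(AGE_GROUPS) * len(SEXES))
    rate = total_deaths / pop
    rows = [(a, s, cause, rate) for a in AGE_GROUPS for s in SEXES]
    return make_country(population_total=pop, mortality_rows=rows), per_cell


# ---------------------------------------------------------------------------
# Deaths averted
# ---------------------------------------------------------------------------

class TestDeathsAverted:
    def test_single_intervention_arithmetic(self):
        country, _ = _country_with_cause_deaths()
        iv = make_intervention(effectiveness=0.7)
        out = deaths_averted(country, [iv], {"I001": (_const(0.5), _const(0.3))}, 2025)
        # 10,000 cause deaths x 0.7 x Δ0.2
        assert out["averted"].sum() == pytest.approx(1_400.0)

    def test_no_coverage_change_averts_nothing(self):
        country, _ = _country_with_cause_deaths()
        iv = make_intervention()
        out = deaths_averted(country, [iv], {"I001": (_const(0.4), _const(0.4))}, 2025)
        assert out["averted"].sum() == 0.0

    def test_residual_combination_not_additive(self):
        country, _ = _country_with_cause_deaths()
        ivs = [
            make_intervention("I001", effectiveness=1.0),
            make_intervention("I002", effectiveness=1.0),
        ]
        trajs = {k: (_const(0.6), _const(0.0)) for k in ("I001", "I002")}
        out = deaths_averted(country, ivs, trajs, 2025)
        # 1 - (1-0.6)^2 = 0.84, not 1.2
        assert out["averted"].sum() == pytest.approx(8_400.0)

    def test_coverage_decrease_warns_and_contributes_zero(self):
        country, _ = _country_with_cause_deaths()
        iv = make_intervention()
        with pytest.warns(UserWarning):
            out = deaths_averted(country, [iv], {"I001": (_const(0.2), _const(0.4))}, 2025)
        assert out["averted"].sum() == 0.0

    def test_missing_trajectory_rejected(self):
        country, _ = _country_with_cause_deaths()
        with pytest.raises(ValueError):
            deaths_averted(country, [make_intervention()], {}, 2025)

    def test_cause_cap_never_exceeded(self):
        country, per_cell = _country_with_cause_deaths(total_deaths=500.0)
        ivs = [make_intervention(f"I{k:03d}", effectiveness=0.99) for k in range(1, 4)]
        trajs = {iv.intervention_id: (_const(1.0), _const(0.0)) for iv in ivs}
        out = deaths_averted(country, ivs, trajs, 2025)
        cell_deaths = 500.0 / 1_000_000.0 * per_cell
        assert (out["averted"] <= cell_deaths + 1e-9).all()


class TestExternalAdjustment:
    def test_cellwise_subtraction(self):
        deaths = pd.Series({("0", "female"): 500.0, ("0", "male"): 300.0})
        averted = pd.Series({("0", "female"): 120.0})
        out = external_cause_adjustment(deaths, averted)
        assert out[("0", "female")] == 380.0
        assert out[("0", "male")] == 300.0

    def test_zero_averted_is_identity(self):
        deaths = pd.Series({("0", "female"): 500.0})
        out = external_cause_adjustment(deaths, pd.Series(dtype=float))
        pd.testing.assert_series_equal(out, deaths)

    def test_overshoot_rejected(self):
        deaths = pd.Series({("0", "female"): 500.0})
        with pytest.raises(ValueError):
            external_cause_adjustment(deaths, pd.Series({("0", "female"): 501.0}))


# ---------------------------------------------------------------------------
# Life tables
# ---------------------------------------------------------------------------

class TestLifeTable:
    def test_qx_formula(self):
        n = np.array([5.0, np.inf])
        lt = build_life_table(np.array([0.01, 0.2]), n, np.array([2.5, np.nan]))
        assert lt.qx[0] == pytest.approx(0.05 / 1.025)
        assert lt.qx[-1] == 1.0

    def test_zero_mx_interval_leaves_lx_unchanged(self):
        n = np.array([5.0, 5.0, np.inf])
        lt = build_life_table(np.array([0.0, 0.01, 0.2]), n)
        assert lt.qx[0] == 0.0
        assert lt.lx[1] == lt.lx[0]

    def test_constant_hazard_matches_exponential_closed_form(self):
        """e0 of a constant-hazard table is 1/m within 0.5 years across
        hazards 0.001-0.1 (single-year ages to an open 110+ group)."""
        n = np.array([1.0] * 110 + [np.inf])
        for m in (0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1):
            ax = np.full(111, 0.5)
            lt = build_life_table(np.full(111, m), n, ax)
            assert lt.e0 == pytest.approx(1.0 / m, abs=0.5)

    def test_invariants_on_generated_schedule(self):
        country = make_country()
        mx = np.full(len(AGE_GROUPS), 0.005)
        lt = build_life_table(mx)
        assert lt.lx[0] == 100_000.0
        assert (np.diff(lt.lx) <= 0).all()
        assert (np.diff(lt.Tx) <= 0).all()
        assert (lt.qx[:-1] <= 1).all() and lt.qx[-1] == 1.0
        assert (lt.Lx >= 0).all() and (lt.ex >= 0).all()

    def test_negative_mx_rejected(self):
        with pytest.raises(ValueError):
            build_life_table(np.array([-0.01, 0.1]), np.array([5.0, np.inf]))

    def test_infant_separation_factor_default(self):
        ax = default_ax(np.array([1.0, 4.0, 5.0, np.inf]))
        assert ax[0] == 0.3
        assert ax[1] == 2.0 and ax[2] == 2.5


class TestLeGain:
    def test_zero_averted_zero_gain(self):
        n = np.array([1.0] * 110 + [np.inf])
        mx = np.full(111, 0.02)
        lt = build_life_table(mx, n, np.full(111, 0.5))
        gain, _ = le_gain(lt, mx, np.zeros(111), np.full(111, 1000.0))
        assert gain == 0.0

    def test_positive_averted_positive_gain(self):
        n = np.array([1.0] * 110 + [np.inf])
        mx = np.full(111, 0.02)
        lt = build_life_table(mx, n, np.full(111, 0.5))
        averted = np.full(111, 5.0)  # 5 of 20 deaths per 1000 py
        gain, _ = le_gain(lt, mx, averted, np.full(111, 1000.0))
        assert gain > 0.0

    def test_halving_hazard_doubles_life_expectancy(self):
        n = np.array([1.0] * 110 + [np.inf])
        mx = np.full(111, 0.02)
        lt = build_life_table(mx, n, np.full(111, 0.5))
        averted = np.full(111, 10.0)  # halves the 0.02 rate at 1000 py
        gain, lt2030 = le_gain(lt, mx, averted, np.full(111, 1000.0))
        assert lt2030.e0 == pytest.approx(100.0, abs=0.5)
        assert gain == pytest.approx(50.0, abs=1.0)

    def test_age_structure_mismatch_rejected(self):
        n = np.array([5.0, np.inf])
        lt = build_life_table(np.array([0.01, 0.2]), n)
        with pytest.raises(ValueError):
            le_gain(lt, np.zeros(3), np.zeros(3), np.ones(3))


# ---------------------------------------------------------------------------
# Healthy life-years
# ---------------------------------------------------------------------------

class TestHly:
    def test_identical_scenarios_zero(self):
        frame = pd.DataFrame({"state": ["a"], "year": [2025], "person_years": [10.0]})
        out = hly_gained(frame, frame.copy(), {"a": 0.2})
        assert float(out.sum()) == 0.0

    def test_person_year_moved_to_healthy(self):
        flat = pd.DataFrame(
            {"state": ["sick", "healthy"], "year": [2025, 2025], "person_years": [1.0, 0.0]}
        )
        up = pd.DataFrame(
            {"state": ["sick", "healthy"], "year": [2025, 2025], "person_years": [0.0, 1.0]}
        )
        out = hly_gained(flat, up, {"sick": 0.2, "healthy": 0.0})
        assert float(out.sum()) == pytest.approx(0.2)

    def test_invalid_weight_rejected(self):
        frame = pd.DataFrame({"state": ["a"], "year": [2025], "person_years": [1.0]})
        with pytest.raises(ValueError):
            hly_gained(frame, frame, {"a": 1.4})

    def test_averted_death_years_bounded_by_horizon(self):
        # one death averted in 2026 with 40 remaining healthy years:
        # accrues only 2026-2030 inclusive = 5 years
        hly = averted_death_life_years(pd.Series({2026: 1.0}), 40.0, horizon_end=2030)
        assert hly == pytest.approx(5.0)
        # short remaining expectancy binds instead
        assert averted_death_life_years(pd.Series({2026: 1.0}), 3.0) == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# Country pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def country_impact():
    country = make_country(
        coverage=0.3,
        n_interventions=3,
        mortality_rows=[
            (a, s, c, r)
            for a in AGE_GROUPS
            for s in SEXES
            for c, r in [("neonatal", 0.001), ("post-neonatal/child", 0.002), ("other", 0.004)]
        ],
    )
    catalog = [
        make_intervention("I001", tier="m1", effectiveness=0.4, cause_group=CauseGroup.NEONATAL),
        make_intervention("I002", tier="m1", effectiveness=0.3, cause_group=CauseGroup.POST_NEONATAL_CHILD),
        make_intervention("I003", tier="m2", effectiveness=0.2, cause_group=CauseGroup.OTHER),
    ]
    return impact_country(country, catalog, MEASURES["m2"])


class TestImpactCountry:
    def test_positive_scaleup_brings_gains(self, country_impact):
        result = country_impact
        assert result.total_deaths_averted > 0
        assert result.le_gain_vs_2015 > 0
        assert result.le_gain_vs_flatline > 0
        assert float(result.hly_by_area.sum()) > 0

    def test_under_five_identity(self, country_impact):
        result = country_impact
        by_cause = result.averted_by_cause()
        assert result.under_five_averted() == pytest.approx(
            by_cause["neonatal"] + by_cause["post-neonatal/child"], rel=1e-12
        )

    def test_flatline_le_equals_baseline(self, country_impact):
        result = country_impact
        assert result.le_2030_flatline == pytest.approx(result.le_2015)

    def test_zero_scaleup_zero_impact(self):
        country = make_country(coverage=1.0, maturity="hs3", n_interventions=1)
        catalog = [make_intervention("I001")]
        res = impact_country(country, catalog, MEASURES["m1"])
        assert res.total_deaths_averted == 0.0
        assert res.le_gain_vs_2015 == pytest.approx(0.0, abs=1e-9)
        assert float(res.hly_by_area.sum()) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_effectiveness(self):
        country = make_country(coverage=0.2, n_interventions=1)
        averted = []
        for eff in (0.1, 0.3, 0.6):
            catalog = [make_intervention("I001", effectiveness=eff)]
            averted.append(impact_country(country, catalog, MEASURES["m1"]).total_deaths_averted)
        assert averted[0] < averted[1] < averted[2]
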