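"""Health impact of PHC scale-up: deaths averted, life expectancy, HLY.

The disease-specific impact machinery of the parent projection tool is
replaced here by a declared coverage-effectiveness stand-in: each
intervention averts a fraction ``effectiveness × Δcoverage`` of the
deaths from its cause group, and interventions acting on the same
cause combine on the residual (1 − Π(1 − eᵢΔcᵢ)), never exceeding the
cause's baseline deaths.  Because the stand-in replaces the original
disease models, absolute impact magnitudes are not comparable with the
published totals; structure, signs and accounting identities are.

Life-expectancy gains use standard abridged period life tables
(mx → qx → lx → Lx → Tx → ex) for 2015 and 2030, with 2030 mortality
net of averted deaths.  Healthy life-years compare person-years lived,
weighted by one minus the disability weight of the health state,
between the flatline and scale-up scenarios, plus the (horizon-bounded)
life-years from deaths and stillbirths averted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CauseGroup, Intervention, MeasureSpec
from .coverage import CoverageTrajectory
from .synthetic_data import AGE_GROUPS, AGE_WIDTHS, SEXES, YEARS, CountryProfile

__all__ = [
    "LifeTable",
    "ImpactResult",
    "DEFAULT_DISABILITY_WEIGHTS",
    "build_life_table",
    "default_ax",
    "deaths_averted",
    "external_cause_adjustment",
    "le_gain",
    "hly_gained",
    "averted_death_life_years",
    "read_disability_weights",
    "impact_country",
]

HORIZON = list(range(2020, 2031))
_RADIX = 100_000.0

#: Stand-in disability weights per cause group (editable; GBD-scale
#: magnitudes for a representative sequela of each area).
DEFAULT_DISABILITY_WEIGHTS: dict[str, float] = {
    "maternal": 0.30,
    "neonatal": 0.40,
    "post-neonatal/child": 0.15,
    "stillbirth": 0.0,
    "NCD": 0.25,
    "cancer": 0.45,
    "TB": 0.33,
    "HIV": 0.27,
    "NTD": 0.12,
    "other": 0.20,
}

#: Causes whose averted deaths are computed outside the main impact loop
#: and subtracted from the 2030 death counts afterwards.
EXTERNAL_CAUSES = ("TB", "NTD", "cancer")


def read_disability_weights(path: str | Path) -> dict[str, float]:
    """Read a two-column delimited table (cause, weight)."""
    df = pd.read_csv(path)
    weights = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    for c, w in weights.items():
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"disability weight for {c!r} outside [0,1]: {w}")
    return weights


# ---------------------------------------------------------------------------
# Life tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Abridged period life table with an open-ended last interval."""

    n: np.ndarray  # interval widths (inf for the last)
    mx: np.ndarray  # central death rates
    ax: np.ndarray  # average years lived in interval by those dying
    qx: np.ndarray
    lx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    @property
    def e0(self) -> float:
        return float(self.ex[0])


def default_ax(n: np.ndarray) -> np.ndarray:
    """Separation factors: half the interval, except 0.3 years for infants."""
    ax = np.asarray(n, dtype=float) * 0.5
    if len(ax) and np.isclose(n[0], 1.0):
        ax[0] = 0.3
    ax[-1] = np.nan  # unused in the open interval
    return ax


def build_life_table(
    mx: np.ndarray, n: np.ndarray | None = None, ax: np.ndarray | None = None
) -> LifeTable:
    """Standard abridged life-table recursion from central death rates.

    qx = n·mx / (1 + (n − ax)·mx), capped at 1; the open last interval
    has qx = 1 and Lx = lx / mx.  A zero mx leaves lx unchanged across
    the interval.
    """
    mx = np.asarray(mx, dtype=float)
    if (mx < 0).any():
        raise ValueError("mx must be non-negative")
    if n is None:
        n = AGE_WIDTHS.copy()
    n = np.asarray(n, dtype=float)
    if n.shape != mx.shape:
        raise ValueError("n and mx must have the same length")
    if not np.isinf(n[-1]):
        raise ValueError("last interval must be open-ended (infinite width)")
    if ax is None:
        ax = default_ax(n)
    ax = np.asarray(ax, dtype=float)

    k = len(mx)
    qx = np.empty(k)
    qx[:-1] = n[:-1] * mx[:-1] / (1.0 + (n[:-1] - ax[:-1]) * mx[:-1])
    qx[:-1] = np.clip(qx[:-1], 0.0, 1.0)
    qx[-1] = 1.0

    lx = np.empty(k)
    lx[0] = _RADIX
    for i in range(1, k):
        lx[i] = lx[i - 1] * (1.0 - qx[i - 1])
    dx = lx * qx

    Lx = np.empty(k)
    Lx[:-1] = n[:-1] * lx[1:] + ax[:-1] * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1] if mx[-1] > 0 else 0.0

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(lx > 0, Tx / np.maximum(lx, 1e-300), 0.0)
    return LifeTable(n=n, mx=mx, ax=ax, qx=qx, lx=lx, Lx=Lx, Tx=Tx, ex=ex)


def le_gain(
    baseline_lt: LifeTable,
    scenario_mx: np.ndarray,
    averted_deaths: np.ndarray,
    person_years: np.ndarray,
) -> tuple[float, LifeTable]:
    """e0 gain from mortality net of averted deaths.

    Averted deaths convert to rate reductions through the person-years
    of each age group; the net 2030 table is rebuilt and its e0
    compared with the baseline table's.  Zero averted deaths with
    unchanged mx give a zero gain.
    """
    scenario_mx = np.asarray(scenario_mx, dtype=float)
    averted_deaths = np.asarray(averted_deaths, dtype=float)
    person_years = np.asarray(person_years, dtype=float)
    if not (scenario_mx.shape == averted_deaths.shape == person_years.shape == baseline_lt.mx.shape):
        raise ValueError("age structures of inputs do not match")
    with np.errstate(invalid="ignore", divide="ignore"):
        reduction = np.where(person_years > 0, averted_deaths / person_years, 0.0)
    net_mx = np.maximum(scenario_mx - reduction, 0.0)
    scenario_lt = build_life_table(net_mx, baseline_lt.n, baseline_lt.ax)
    return scenario_lt.e0 - baseline_lt.e0, scenario_lt


# ---------------------------------------------------------------------------
# Deaths averted
# ---------------------------------------------------------------------------

def _combined_averted_fraction(
    interventions: list[Intervention], delta_cov: dict[str, float]
) -> dict[str, float]:
    """Residual combination of per-intervention averted fractions by cause."""
    fractions: dict[str, float] = {}
    residual: dict[str, float] = {}
    for iv in interventions:
        d = delta_cov.get(iv.intervention_id, 0.0)
        if d < 0:
            warnings.warn(
                f"coverage decrease for {iv.intervention_id}; treated as zero impact",
                stacklevel=3,
            )
            d = 0.0
        cause = iv.cause_group.value
        residual[cause] = residual.get(cause, 1.0) * (1.0 - iv.effectiveness * d)
    for cause, r in residual.items():
        fractions[cause] = 1.0 - r
    return fractions


def deaths_averted(
    country: CountryProfile,
    interventions: list[Intervention],
    trajectories: dict[str, tuple[CoverageTrajectory, CoverageTrajectory]],
    year: int,
) -> pd.DataFrame:
    """Deaths averted in one year, by cause, age group and sex.

    ``trajectories`` maps intervention id to its (scale-up, flatline)
    pair.  For each cause, the combined averted fraction is
    1 − Π(1 − effectiveness × Δcoverage) over the interventions
    addressing it, applied to the cause's deaths; the result can never
    exceed the cause's baseline deaths.
    """
    missing = [iv.intervention_id for iv in interventions if iv.intervention_id not in trajectories]
    if missing:
        raise ValueError(f"trajectories missing for interventions: {missing[:5]}")
    delta = {
        iid: traj_s.at(year) - traj_f.at(year)
        for iid, (traj_s, traj_f) in trajectories.items()
    }
    fractions = _combined_averted_fraction(interventions, delta)

    py = country.population_by_age_sex(year)
    mr = country.mortality_rate
    rows = []
    for cause, frac in fractions.items():
        sub = mr[mr["cause"] == cause]
        for _, r in sub.iterrows():
            deaths = r["rate"] * py.get((r["age_group"], r["sex"]), 0.0)
            rows.append(
                {
                    "cause": cause,
                    "age_group": r["age_group"],
                    "sex": r["sex"],
                    "year": year,
                    "averted": deaths * frac,
                }
            )
    return pd.DataFrame(rows, columns=["cause", "age_group", "sex", "year", "averted"])


def external_cause_adjustment(
    deaths_2030: pd.Series, averted_external: pd.Series
) -> pd.Series:
    """Cell-wise subtraction of externally modelled averted deaths.

    Some cause areas (tuberculosis, NTDs, cervical-cancer screening)
    are modelled outside the main impact loop; their averted deaths
    are subtracted from the 2030 death counts by age and sex before
    the life table is built.
    """
    averted = averted_external.reindex(deaths_2030.index).fillna(0.0)
    if (averted - deaths_2030 > 1e-9).any():
        bad = averted[averted - deaths_2030 > 1e-9].index.tolist()[:3]
        raise ValueError(f"averted deaths exceed deaths in cells {bad}")
    return deaths_2030 - averted


# ---------------------------------------------------------------------------
# Healthy life-years
# ---------------------------------------------------------------------------

def hly_gained(
    flatline_pop_health: pd.DataFrame,
    scaleup_pop_health: pd.DataFrame,
    disability_weights: dict[str, float],
) -> pd.Series:
    """Healthy life-years gained by health state, scale-up vs flatline.

    Inputs are tidy person-year tables with columns
    (state, year, person_years).  Each person-year counts
    (1 − disability weight of its state); the gain is the scale-up
    total minus the flatline total, reported by state.  Identical
    scenarios give zero.
    """
    for w in disability_weights.values():
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"disability weight outside [0,1]: {w}")

    def _weighted(df: pd.DataFrame) -> pd.Series:
        missing = set(df["state"]) - set(disability_weights)
        if missing:
            raise ValueError(f"no disability weight for states {sorted(missing)}")
        w = df["state"].map(disability_weights)
        return (df["person_years"] * (1.0 - w)).groupby(df["state"]).sum()

    hly_s = _weighted(scaleup_pop_health)
    hly_f = _weighted(flatline_pop_health)
    return hly_s.sub(hly_f, fill_value=0.0)


def averted_death_life_years(
    averted_by_year: pd.Series, remaining_healthy_le: float, horizon_end: int = 2030
) -> float:
    """Healthy life-years accrued by averted deaths within the horizon.

    A death averted in year y accrues healthy years until the earlier
    of the remaining healthy life expectancy and the end of the
    projection horizon (inclusive).
    """
    if remaining_healthy_le < 0:
        raise ValueError("remaining healthy life expectancy must be non-negative")
    total = 0.0
    for year, deaths in averted_by_year.items():
        years_left = max(0.0, horizon_end + 1 - int(year))
        total += float(deaths) * min(remaining_healthy_le, years_left)
    return total


# ---------------------------------------------------------------------------
# Country-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class ImpactResult:
    """Impact of one country-measure over the projection horizon."""

    country_id: str
    measure_id: str
    deaths_averted_by_cause_year: pd.DataFrame  # cause, year, averted
    le_2015: float
    le_2030_flatline: float
    le_2030_scaleup: float
    hly_by_area: pd.Series

    @property
    def total_deaths_averted(self) -> float:
        return float(self.deaths_averted_by_cause_year["averted"].sum())

    @property
    def le_gain_vs_2015(self) -> float:
        return self.le_2030_scaleup - self.le_2015

    @property
    def le_gain_vs_flatline(self) -> float:
        return self.le_2030_scaleup - self.le_2030_flatline

    def averted_by_cause(self) -> pd.Series:
        return self.deaths_averted_by_cause_year.groupby("cause")["averted"].sum()

    def under_five_averted(self) -> float:
        """Accounting identity: under-5 = neonatal + post-neonatal/child."""
        by_cause = self.averted_by_cause()
        return float(
            by_cause.get(CauseGroup.NEONATAL.value, 0.0)
            + by_cause.get(CauseGroup.POST_NEONATAL_CHILD.value, 0.0)
        )


def impact_country(
    country: CountryProfile,
    catalog: list[Intervention],
    measure: MeasureSpec,
    disability_weights: dict[str, float] | None = None,
) -> ImpactResult:
    """Full impact projection for one country under one measure."""
    from .coverage import build_trajectory, flatline  # local to avoid clutter

    weights = disability_weights or DEFAULT_DISABILITY_WEIGHTS
    member = [iv for iv in catalog if iv.in_measure(measure.measure_id)]
    causes = [c.value for c in CauseGroup]

    # Rates and person-years as dense arrays (cause × age × sex).
    mr = country.mortality_rate.set_index(["cause", "age_group", "sex"])["rate"]
    rate = np.zeros((len(causes), len(AGE_GROUPS), len(SEXES)))
    for ci, c in enumerate(causes):
        for ai, a in enumerate(AGE_GROUPS):
            for si, s in enumerate(SEXES):
                rate[ci, ai, si] = mr.get((c, a, s), 0.0)

    pop = country.population.pivot_table(
        index=["age_group", "sex"], columns="year", values="population"
    )
    pop = pop.reindex(
        pd.MultiIndex.from_product([AGE_GROUPS, SEXES], names=["age_group", "sex"])
    )
    py = pop.to_numpy().reshape(len(AGE_GROUPS), len(SEXES), -1)  # age × sex × years
    year_cols = list(pop.columns)

    # Coverage deltas per member intervention and year.
    cov_s = np.vstack(
        [
            build_trajectory(
                float(country.baseline_coverage.get(iv.intervention_id, 0.0)),
                country.maturity,
            ).values
            for iv in member
        ]
    ) if member else np.zeros((0, len(YEARS)))
    base = np.array(
        [float(country.baseline_coverage.get(iv.intervention_id, 0.0)) for iv in member]
    )
    dcov = cov_s - base[:, None]

    eff = np.array([iv.effectiveness for iv in member])
    cause_idx = np.array([causes.index(iv.cause_group.value) for iv in member], dtype=int)

    # Combined averted fraction per cause and year (residual combination).
    frac = np.zeros((len(causes), len(YEARS)))
    for ci in range(len(causes)):
        sel = cause_idx == ci
        if sel.any():
            frac[ci] = 1.0 - np.prod(1.0 - eff[sel, None] * dcov[sel], axis=0)

    rows = []
    averted_2030 = np.zeros((len(causes), len(AGE_GROUPS), len(SEXES)))
    for y in HORIZON:
        k = year_cols.index(y)
        deaths_cy = np.einsum("cas,as->c", rate, py[:, :, k])
        averted_cy = deaths_cy * frac[:, YEARS.index(y)]
        for ci, c in enumerate(causes):
            rows.append({"cause": c, "year": y, "averted": float(averted_cy[ci])})
        if y == 2030:
            averted_2030 = rate * py[None, :, :, k] * frac[:, YEARS.index(y), None, None]
    by_cause_year = pd.DataFrame(rows)

    # --- life expectancy --------------------------------------------------
    sb = causes.index(CauseGroup.STILLBIRTH.value)
    live_causes = [ci for ci in range(len(causes)) if ci != sb]
    k2030 = year_cols.index(2030)
    py2030 = py[:, :, k2030]
    mx_all = rate[live_causes].sum(axis=0)  # age × sex

    main = [ci for ci in live_causes if causes[ci] not in EXTERNAL_CAUSES]
    ext = [ci for ci in live_causes if causes[ci] in EXTERNAL_CAUSES]

    gains = {}
    for scenario in ("flatline", "scaleup"):
        e0_by_sex = []
        for si in range(len(SEXES)):
            lt2015 = build_life_table(mx_all[:, si])
            if scenario == "flatline":
                e0_by_sex.append((lt2015.e0, lt2015.e0))
                continue
            deaths2030 = mx_all[:, si] * py2030[:, si]
            averted_main = averted_2030[main, :, si].sum(axis=0)
            net_main = np.maximum(deaths2030 - averted_main, 0.0)
            # external causes subtracted afterwards, mirroring the
            # outside-the-tool treatment of TB / NTD / cervical screening
            idx = pd.Index(AGE_GROUPS, name="age_group")
            net = external_cause_adjustment(
                pd.Series(net_main, index=idx),
                pd.Series(averted_2030[ext, :, si].sum(axis=0), index=idx),
            ).to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                net_mx = np.where(py2030[:, si] > 0, net / py2030[:, si], 0.0)
            lt2030 = build_life_table(net_mx)
            e0_by_sex.append((lt2015.e0, lt2030.e0))
        e0_2015 = float(np.mean([t[0] for t in e0_by_sex]))
        e0_2030 = float(np.mean([t[1] for t in e0_by_sex]))
        gains[scenario] = (e0_2015, e0_2030)

    le_2015 = gains["scaleup"][0]
    le_2030_flatline = gains["flatline"][1]
    le_2030_scaleup = gains["scaleup"][1]

    # --- healthy life-years ----------------------------------------------
    # Morbidity relief: person-years in each cause's disabled state are
    # cases in need not effectively covered; scale-up moves them to the
    # paired healthy state.
    lt_ref = build_life_table(mx_all.mean(axis=1))
    hle_child = float(lt_ref.ex[0]) * (1.0 - 0.1)  # crude health adjustment
    hle_adult = float(lt_ref.ex[6]) * (1.0 - 0.1) if len(lt_ref.ex) > 6 else 30.0
    flat_rows, scale_rows = [], []
    tpf = np.array([iv.target_pop_fraction for iv in member])
    inf_ = np.array([iv.in_need_fraction for iv in member])
    for y in HORIZON:
        k = year_cols.index(y)
        pop_tot = py[:, :, k].sum()
        in_need = pop_tot * tpf * inf_
        disabled_f = in_need * (1.0 - eff * base)
        disabled_s = in_need * (1.0 - eff * cov_s[:, YEARS.index(y)]) if member else np.array([])
        for ci, c in enumerate(causes):
            sel = cause_idx == ci
            if not sel.any():
                continue
            need = float(in_need[sel].sum())
            df_ = float(disabled_f[sel].sum())
            ds_ = float(disabled_s[sel].sum())
            flat_rows += [
                {"state": f"{c}:disabled", "year": y, "person_years": df_},
                {"state": f"{c}:healthy", "year": y, "person_years": need - df_},
            ]
            scale_rows += [
                {"state": f"{c}:disabled", "year": y, "person_years": ds_},
                {"state": f"{c}:healthy", "year": y, "person_years": need - ds_},
            ]
    state_weights = {}
    for c in causes:
        state_weights[f"{c}:disabled"] = weights.get(c, 0.2)
        state_weights[f"{c}:healthy"] = 0.0
    morbidity = (
        hly_gained(pd.DataFrame(flat_rows), pd.DataFrame(scale_rows), state_weights)
        if flat_rows
        else pd.Series(dtype=float)
    )
    hly_area = {}
    for c in causes:
        gain = float(
            morbidity.get(f"{c}:disabled", 0.0) + morbidity.get(f"{c}:healthy", 0.0)
        )
        averted_series = by_cause_year[by_cause_year["cause"] == c].set_index("year")["averted"]
        hle = hle_child if c in ("neonatal", "post-neonatal/child", "stillbirth") else hle_adult
        gain += averted_death_life_years(averted_series, hle)
        hly_area[c] = gain
    hly_by_area = pd.Series(hly_area).clip(lower=0.0)

    return ImpactResult(
        country_id=country.country_id,
        measure_id=measure.measure_id,
        deaths_averted_by_cause_year=by_cause_year,
        le_2015=le_2015,
        le_2030_flatline=le_2030_flatline,
        le_2030_scaleup=le_2030_scaleup,
        hly_by_area=hly_by_area,
    )
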