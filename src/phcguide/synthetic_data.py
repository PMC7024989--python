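"""Synthetic LMIC cohort generator.

The projection framework was built for a cohort of 67 low- and
middle-income countries whose underlying country inputs (demography,
expenditure, coverage, prices, cause-of-death rates) are not public.
This module generates reproducible synthetic country profiles with the
statistical structure the downstream stages assume:

* three income groups (low, lower-middle, upper-middle) and five
  system-maturity categories (conflict, vulnerable, hs1, hs2, hs3);
* income-graded GDP, prices, workforce density and baseline coverage
  (poorer groups stochastically lower) and income-graded mortality
  (poorer groups higher);
* abridged-age population surfaces by sex for calendar years
  2015-2030;
* a short historical series of current health expenditure as % of GDP
  so the business-as-usual financing trend is well defined.

Every draw flows from one :class:`numpy.random.Generator` seeded from
``GeneratorConfig.seed``, so identical configs give bit-identical
cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CauseGroup, Intervention, Platform

__all__ = [
    "AGE_GROUPS",
    "AGE_WIDTHS",
    "SEXES",
    "INCOME_GROUPS",
    "MATURITIES",
    "YEARS",
    "ConfigurationError",
    "CountryProfile",
    "GeneratorConfig",
    "generate_countries",
    "generate_catalog",
    "write_profiles",
]

#: Abridged age groups: infant, child, then 5-year bands to the open 85+ group.
AGE_GROUPS: list[str] = (
    ["0", "1-4"]
    + [f"{lo}-{lo + 4}" for lo in range(5, 85, 5)]
    + ["85+"]
)
#: Interval widths in years (infinite for the open-ended last interval).
AGE_WIDTHS: np.ndarray = np.array([1.0, 4.0] + [5.0] * 16 + [np.inf])
#: Interval midpoints used by the Gompertz schedule (85+ treated as 85-100).
_AGE_MIDS: np.ndarray = np.array([0.5, 3.0] + [lo + 2.5 for lo in range(5, 85, 5)] + [92.5])

SEXES = ("female", "male")
INCOME_GROUPS = ("low", "lower-middle", "upper-middle")
MATURITIES = ("conflict", "vulnerable", "hs1", "hs2", "hs3")
YEARS = list(range(2015, 2031))

CADRES = ("doctor", "nurse_midwife", "other")


class ConfigurationError(ValueError):
    """Invalid generator or run configuration."""


@dataclass
class CountryProfile:
    """One synthetic (or user-supplied) country.

    Monetary values are constant 2014 US$.  ``mortality_rate`` is a
    tidy frame (age_group, sex, cause) -> deaths per person-year; the
    ``stillbirth`` cause is carried on the infant rows and is excluded
    from all-cause rates for life tables (stillbirths are not deaths
    of the living population).
    """

    country_id: str
    income_group: str
    maturity: str
    population: pd.DataFrame  # columns: year, age_group, sex, population
    gdp_per_capita: pd.Series  # index year 2015-2030
    che_pct_gdp: pd.Series  # historical, index year 2015-2019
    current_phc_exp_per_capita: float  # recurrent only
    workforce_density: dict[str, float]  # per 1000, by cadre
    baseline_visits_per_capita: float
    baseline_coverage: pd.Series  # index intervention_id, values in [0,1]
    mortality_rate: pd.DataFrame  # columns: age_group, sex, cause, rate
    unit_price_index: float
    deflator: float = 1.0

    # -- convenience views -------------------------------------------------
    def total_population(self, year: int) -> float:
        pop = self.population
        return float(pop.loc[pop["year"] == year, "population"].sum())

    def population_by_age_sex(self, year: int) -> pd.DataFrame:
        pop = self.population
        out = pop.loc[pop["year"] == year, ["age_group", "sex", "population"]]
        return out.set_index(["age_group", "sex"])["population"]

    def births(self, year: int) -> float:
        """Approximate live births as the infant-age population."""
        pop = self.population
        m = (pop["year"] == year) & (pop["age_group"] == "0")
        return float(pop.loc[m, "population"].sum())

    def all_cause_mx(self) -> pd.Series:
        """All-cause central death rate by (age_group, sex), stillbirths excluded."""
        mr = self.mortality_rate
        mr = mr[mr["cause"] != CauseGroup.STILLBIRTH.value]
        return mr.groupby(["age_group", "sex"], sort=False)["rate"].sum()

    def validate(self) -> list[str]:
        problems = []
        if self.income_group not in INCOME_GROUPS:
            problems.append(f"income_group {self.income_group!r} unknown")
        if self.maturity not in MATURITIES:
            problems.append(f"maturity {self.maturity!r} unknown")
        if (self.population["population"] <= 0).any():
            problems.append("non-positive population cell")
        if not self.che_pct_gdp.between(0, 25, inclusive="neither").all():
            problems.append("che_pct_gdp outside (0, 25)")
        if len(self.che_pct_gdp) < 5 or self.che_pct_gdp.index.max() != 2019:
            problems.append("che_pct_gdp must span >=5 years ending 2019")
        if not self.baseline_coverage.between(0, 1).all():
            problems.append("baseline_coverage outside [0,1]")
        if (self.mortality_rate["rate"] < 0).any():
            problems.append("negative mortality rate")
        if self.unit_price_index <= 0:
            problems.append("unit_price_index must be positive")
        return problems


# ---------------------------------------------------------------------------
# Generator configuration: group-level priors.
# ---------------------------------------------------------------------------

def _default_group_mix() -> dict[tuple[str, str], float]:
    # Income split roughly matching an LMIC cohort; uniform over maturity
    # within each income group (the true composition is unpublished).
    income_share = {"low": 0.35, "lower-middle": 0.40, "upper-middle": 0.25}
    return {
        (ig, m): income_share[ig] / len(MATURITIES)
        for ig in INCOME_GROUPS
        for m in MATURITIES
    }


def _default_coverage_prior() -> dict[str, tuple[float, float]]:
    # (mean, concentration) of a beta prior on baseline coverage by maturity.
    return {
        "conflict": (0.22, 12.0),
        "vulnerable": (0.30, 12.0),
        "hs1": (0.38, 12.0),
        "hs2": (0.48, 12.0),
        "hs3": (0.58, 12.0),
    }


def _default_gdp_prior() -> dict[str, tuple[float, float]]:
    # (log-mean, log-sd) of GDP per capita in 2014 US$ by income group.
    return {
        "low": (np.log(700.0), 0.35),
        "lower-middle": (np.log(2300.0), 0.35),
        "upper-middle": (np.log(7500.0), 0.30),
    }


def _default_mortality_family() -> dict[str, dict[str, float]]:
    # Two-parameter Gompertz adult schedule (level a, slope b per year of
    # age) plus separate infant / child levels, per income group.
    return {
        "low": {"a": 8.0e-5, "b": 0.090, "infant": 0.055, "child": 0.0065, "stillbirth": 0.025},
        "lower-middle": {"a": 6.5e-5, "b": 0.092, "infant": 0.032, "child": 0.0032, "stillbirth": 0.017},
        "upper-middle": {"a": 5.0e-5, "b": 0.094, "infant": 0.012, "child": 0.0010, "stillbirth": 0.008},
    }


@dataclass
class GeneratorConfig:
    """Priors and bookkeeping for the synthetic cohort."""

    n_countries: int = 67
    seed: int = 0
    n_interventions: int = 188
    group_mix: dict[tuple[str, str], float] = field(default_factory=_default_group_mix)
    coverage_prior: dict[str, tuple[float, float]] = field(default_factory=_default_coverage_prior)
    gdp_prior: dict[str, tuple[float, float]] = field(default_factory=_default_gdp_prior)
    mortality_family: dict[str, dict[str, float]] = field(default_factory=_default_mortality_family)

    def validate(self) -> None:
        if self.n_countries < 1:
            raise ConfigurationError("n_countries must be >= 1")
        total = sum(self.group_mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ConfigurationError(f"group_mix proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.group_mix.values()):
            raise ConfigurationError("group_mix proportions must be non-negative")


# Income-graded multipliers applied on top of the maturity coverage prior,
# price index, workforce and visit levels.  Means chosen to mirror the
# magnitude ordering of published LMIC guide posts (workforce densities
# near 1.4 / 4.6 / 7.9 per 1000).
_INCOME_COVERAGE_FACTOR = {"low": 0.85, "lower-middle": 1.0, "upper-middle": 1.15}
_PRICE_INDEX_MEAN = {"low": 0.80, "lower-middle": 1.00, "upper-middle": 1.40}
_WORKFORCE_MEAN = {"low": 1.4, "lower-middle": 4.6, "upper-middle": 7.9}  # per 1000
_VISITS_MEAN = {"low": 1.7, "lower-middle": 1.7, "upper-middle": 5.2}  # per capita
_PHC_EXP_MEAN = {"low": 25.0, "lower-middle": 34.0, "upper-middle": 110.0}  # US$ pc
_CHE_PCT_MEAN = {"low": 5.5, "lower-middle": 5.3, "upper-middle": 5.8}
_POP_GROWTH = {"low": 0.027, "lower-middle": 0.015, "upper-middle": 0.006}
_GDP_GROWTH_MEAN = 0.030

# Stylised abridged age-structure templates (fractions over AGE_GROUPS).
def _age_template(income_group: str) -> np.ndarray:
    # Younger pyramids in poorer groups: geometric decay over 5-year bands.
    decay = {"low": 0.82, "lower-middle": 0.88, "upper-middle": 0.94}[income_group]
    bands = np.arange(18)  # 0-4, 5-9, ..., 85+
    w5 = decay ** bands
    # old-age attrition thins the bands past 65 well below the young-age decay
    w5 *= np.where(bands > 13, 0.55 ** (bands - 13), 1.0)
    shares = np.empty(len(AGE_GROUPS))
    shares[0] = w5[0] * 0.2  # infant slice of the 0-4 band
    shares[1] = w5[0] * 0.8
    shares[2:] = w5[1:]
    return shares / shares.sum()


def _cause_weights(age_index: int, sex: str) -> dict[str, float]:
    """Stylised cause-of-death composition of all-cause mortality by age."""
    if age_index == 0:
        return {"neonatal": 0.55, "post-neonatal/child": 0.30, "other": 0.15}
    if age_index == 1:
        return {"post-neonatal/child": 0.72, "NTD": 0.08, "HIV": 0.03, "other": 0.17}
    if age_index <= 3:  # 5-14
        return {"other": 0.62, "NTD": 0.10, "HIV": 0.05, "TB": 0.08, "NCD": 0.15}
    if age_index <= 10:  # 15-49
        w = {"TB": 0.16, "HIV": 0.16, "NCD": 0.26, "cancer": 0.06, "NTD": 0.03}
        if sex == "female":
            w["maternal"] = 0.12
        w["other"] = 1.0 - sum(w.values())
        return w
    return {"NCD": 0.45, "cancer": 0.15, "TB": 0.05, "other": 0.35}


def _make_country(
    rng: np.random.Generator,
    idx: int,
    income_group: str,
    maturity: str,
    config: GeneratorConfig,
) -> CountryProfile:
    country_id = f"C{idx:03d}"

    # --- economy ---------------------------------------------------------
    mu, sd = config.gdp_prior[income_group]
    gdp0 = float(rng.lognormal(mu, sd))
    growth = rng.normal(_GDP_GROWTH_MEAN, 0.008)
    gdp = pd.Series(
        gdp0 * (1.0 + growth) ** (np.array(YEARS) - 2015), index=YEARS, name="gdp_per_capita"
    )

    che0 = float(np.clip(rng.normal(_CHE_PCT_MEAN[income_group], 1.0), 1.5, 12.0))
    trend = rng.normal(0.05, 0.04)
    hist_years = np.arange(2015, 2020)
    che = che0 + trend * (hist_years - 2015) + rng.normal(0.0, 0.08, size=5)
    che = pd.Series(np.clip(che, 0.5, 24.0), index=hist_years, name="che_pct_gdp")

    # --- demography ------------------------------------------------------
    total0 = float(rng.lognormal(np.log(18e6), 1.0))
    shares = _age_template(income_group)
    g = _POP_GROWTH[income_group] + rng.normal(0.0, 0.003)
    rows = []
    for year in YEARS:
        tot = total0 * (1.0 + g) ** (year - 2015)
        for a, share in zip(AGE_GROUPS, shares):
            for sex, frac in zip(SEXES, (0.497, 0.503)):
                rows.append((year, a, sex, tot * share * frac))
    population = pd.DataFrame(rows, columns=["year", "age_group", "sex", "population"])

    # --- mortality -------------------------------------------------------
    fam = config.mortality_family[income_group]
    level_noise = float(rng.lognormal(0.0, 0.12))
    mx_all = fam["a"] * np.exp(fam["b"] * _AGE_MIDS) * level_noise
    mx_all[0] = fam["infant"] * level_noise
    mx_all[1] = fam["child"] * level_noise
    mrows = []
    for ai, a in enumerate(AGE_GROUPS):
        for sex in SEXES:
            sex_adj = 1.08 if sex == "male" and ai >= 4 else 1.0
            for cause, w in _cause_weights(ai, sex).items():
                mrows.append((a, sex, cause, mx_all[ai] * sex_adj * w))
        if a == "0":
            for sex in SEXES:
                mrows.append((a, sex, "stillbirth", fam["stillbirth"] * level_noise))
    mortality = pd.DataFrame(mrows, columns=["age_group", "sex", "cause", "rate"])

    # --- system & coverage ----------------------------------------------
    cov_mean, conc = config.coverage_prior[maturity]
    cov_mean = float(np.clip(cov_mean * _INCOME_COVERAGE_FACTOR[income_group], 0.05, 0.9))
    alpha, beta = cov_mean * conc, (1.0 - cov_mean) * conc
    coverage = pd.Series(
        rng.beta(alpha, beta, size=config.n_interventions),
        index=[f"I{i + 1:03d}" for i in range(config.n_interventions)],
        name="baseline_coverage",
    ).clip(0.0, 1.0)

    density_total = float(rng.lognormal(np.log(_WORKFORCE_MEAN[income_group]), 0.25))
    workforce = {
        "doctor": density_total * 0.18,
        "nurse_midwife": density_total * 0.52,
        "other": density_total * 0.30,
    }

    return CountryProfile(
        country_id=country_id,
        income_group=income_group,
        maturity=maturity,
        population=population,
        gdp_per_capita=gdp,
        che_pct_gdp=che,
        current_phc_exp_per_capita=float(
            rng.lognormal(np.log(_PHC_EXP_MEAN[income_group]), 0.30)
        ),
        workforce_density=workforce,
        baseline_visits_per_capita=float(
            rng.lognormal(np.log(_VISITS_MEAN[income_group]), 0.25)
        ),
        baseline_coverage=coverage,
        mortality_rate=mortality,
        unit_price_index=float(rng.lognormal(np.log(_PRICE_INDEX_MEAN[income_group]), 0.15)),
    )


def generate_countries(config: GeneratorConfig) -> list[CountryProfile]:
    """Draw a reproducible cohort of synthetic country profiles.

    Identical configs (including seed) return bit-identical cohorts.
    Group means obey the income gradient: lower income groups have
    lower coverage, prices and workforce density and higher mortality.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_mix.keys())
    probs = np.array([config.group_mix[gkey] for gkey in groups])
    probs = probs / probs.sum()
    assignments = rng.choice(len(groups), size=config.n_countries, p=probs)
    profiles = []
    for i, gi in enumerate(assignments):
        income_group, maturity = groups[int(gi)]
        profiles.append(_make_country(rng, i, income_group, maturity, config))
    return profiles


# ---------------------------------------------------------------------------
# Intervention catalog generation
# ---------------------------------------------------------------------------

# Named catalog entries kept verbatim for documentation fidelity: platform,
# narrowest measure they belong to, cause group acted on.
_NAMED_INTERVENTIONS: list[tuple[str, Platform, str, str]] = [
    ("Tobacco and alcohol taxation", Platform.POLICY_POPULATION, "m1", "NCD"),
    ("Breastfeeding promotion campaign", Platform.POLICY_POPULATION, "m1", "post-neonatal/child"),
    ("Safe sex behaviour change campaign", Platform.POLICY_POPULATION, "m1", "HIV"),
    ("Childhood vaccination programme", Platform.OUTREACH, "m1", "post-neonatal/child"),
    ("Family planning", Platform.OUTREACH, "m1", "maternal"),
    ("Nutrition counselling and micronutrient supplementation", Platform.OUTREACH, "m1", "post-neonatal/child"),
    ("Oral antibiotics for pneumonia", Platform.FIRST_LEVEL_CLINICAL, "m1", "post-neonatal/child"),
    ("First-line tuberculosis treatment", Platform.FIRST_LEVEL_CLINICAL, "m1", "TB"),
    ("Standard glycaemic control for diabetes", Platform.FIRST_LEVEL_CLINICAL, "m1", "NCD"),
    ("Smoking cessation counselling", Platform.FIRST_LEVEL_CLINICAL, "m1", "NCD"),
    ("Mammography screening", Platform.FIRST_LEVEL_AND_ABOVE, "m1", "cancer"),
    ("Asthma and COPD treatment", Platform.FIRST_LEVEL_AND_ABOVE, "m1", "NCD"),
    ("Cervical cancer screening", Platform.FIRST_LEVEL_AND_ABOVE, "m1", "cancer"),
    ("Normal delivery care", Platform.FIRST_LEVEL_CLINICAL, "m2", "neonatal"),
    ("Basic neonate resuscitation", Platform.FIRST_LEVEL_CLINICAL, "m2", "neonatal"),
    ("Basic emergency obstetric care", Platform.FIRST_LEVEL_AND_ABOVE, "m2", "maternal"),
    ("Water, sanitation, and hygiene", Platform.CROSS_SECTORAL, "m3", "post-neonatal/child"),
    ("Indoor air pollution reduction", Platform.CROSS_SECTORAL, "m3", "NCD"),
    ("Food safety", Platform.CROSS_SECTORAL, "m3", "post-neonatal/child"),
]

_CAUSE_POOL = [c.value for c in CauseGroup]
_CAUSE_PROBS = np.array([0.06, 0.08, 0.16, 0.05, 0.22, 0.07, 0.08, 0.09, 0.06, 0.13])
_CAUSE_PROBS = _CAUSE_PROBS / _CAUSE_PROBS.sum()

_PLATFORM_POOL = [
    Platform.POLICY_POPULATION,
    Platform.OUTREACH,
    Platform.FIRST_LEVEL_CLINICAL,
    Platform.FIRST_LEVEL_AND_ABOVE,
]
_PLATFORM_PROBS = np.array([0.12, 0.20, 0.45, 0.23])


def generate_catalog(
    n_interventions: int = 188,
    seed: int = 0,
    measure_counts: tuple[int, int, int] | None = None,
) -> list[Intervention]:
    """Generate a synthetic catalog with nested measure membership.

    The default emulates the parent model's 188-intervention package,
    of which 143 fall in measure 1, 152 in measure 2 and 160 in
    measure 3 (nested: M1 ⊆ M2 ⊆ M3; the remainder is specialised
    care outside all PHC measures).  Named exemplar interventions
    (vaccination, family planning, normal delivery, basic emergency
    obstetric care, water-sanitation, ...) are always included; the
    rest are generically named with randomised costing parameters.
    """
    if measure_counts is None:
        if n_interventions == 188:
            measure_counts = (143, 152, 160)
        else:  # keep the default membership proportions at other sizes
            measure_counts = tuple(
                max(1, round(n_interventions * c / 188)) for c in (143, 152, 160)
            )
    n1, n2, n3 = measure_counts
    if not (1 <= n1 <= n2 <= n3 <= n_interventions):
        raise ConfigurationError(
            f"measure counts must satisfy 1 <= m1 <= m2 <= m3 <= n: {measure_counts}"
        )
    named = [t for t in _NAMED_INTERVENTIONS if len(_NAMED_INTERVENTIONS) <= n_interventions]
    if n_interventions < len(_NAMED_INTERVENTIONS):
        named = []  # tiny catalogs are fully generic
    rng = np.random.default_rng(seed)

    # Membership tiers by position after sorting: the first n1 are m1,
    # the next (n2-n1) are m2-only, the next (n3-n2) m3-only, the rest
    # outside all measures.  Named entries are pinned to their tier.
    tiers = np.array(["none"] * n_interventions, dtype=object)
    tiers[:n1] = "m1"
    tiers[n1:n2] = "m2"
    tiers[n2:n3] = "m3"

    catalog: list[Intervention] = []
    tier_slots = {"m1": list(range(0, n1)), "m2": list(range(n1, n2)), "m3": list(range(n2, n3))}
    names: dict[int, tuple[str, Platform, str]] = {}
    for name, platform, tier, cause in named:
        if tier_slots.get(tier):
            slot = tier_slots[tier].pop(0)
            names[slot] = (name, platform, cause)

    for i in range(n_interventions):
        tier = tiers[i]
        if i in names:
            name, platform, cause = names[i]
        else:
            cause = str(rng.choice(_CAUSE_POOL, p=_CAUSE_PROBS))
            if tier == "m3":
                platform = Platform.CROSS_SECTORAL
                name = f"Cross-sectoral intervention {i + 1}"
            elif tier == "none":
                platform = Platform.FIRST_LEVEL_AND_ABOVE
                name = f"Specialised service {i + 1}"
            else:
                platform = _PLATFORM_POOL[
                    int(rng.choice(len(_PLATFORM_POOL), p=_PLATFORM_PROBS / _PLATFORM_PROBS.sum()))
                ]
                name = f"Essential service {i + 1}"
        catalog.append(
            Intervention(
                intervention_id=f"I{i + 1:03d}",
                name=name,
                platform=platform,
                in_m1=tier == "m1",
                in_m2=tier in ("m1", "m2"),
                in_m3=tier in ("m1", "m2", "m3"),
                target_pop_fraction=float(rng.beta(2.0, 6.0)),
                in_need_fraction=float(rng.beta(2.0, 4.0)),
                units_per_case=float(rng.lognormal(np.log(3.0), 0.8)),
                commodity_price=float(rng.lognormal(np.log(0.6), 0.9)),
                visits_per_case=float(rng.lognormal(np.log(0.7), 0.5)),
                minutes_per_visit=float(rng.uniform(10.0, 35.0)),
                capital_share=float(rng.beta(1.5, 10.0)),
                effectiveness=float(rng.beta(1.2, 28.0)),
                cause_group=CauseGroup(cause),
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# Tidy-table export
# ---------------------------------------------------------------------------

def write_profiles(profiles: list[CountryProfile], out_dir: str | Path, manifest: dict | None = None) -> None:
    """Write a cohort as tidy delimited tables plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    demog = pd.concat(
        [p.population.assign(country_id=p.country_id) for p in profiles], ignore_index=True
    )
    demog.to_csv(out / "demography.csv", index=False)

    scalars = pd.DataFrame(
        {
            "country_id": [p.country_id for p in profiles],
            "income_group": [p.income_group for p in profiles],
            "maturity": [p.maturity for p in profiles],
            "gdp_per_capita_2015": [p.gdp_per_capita[2015] for p in profiles],
            "current_phc_exp_per_capita": [p.current_phc_exp_per_capita for p in profiles],
            "baseline_visits_per_capita": [p.baseline_visits_per_capita for p in profiles],
            "unit_price_index": [p.unit_price_index for p in profiles],
            "workers_per_1000": [sum(p.workforce_density.values()) for p in profiles],
        }
    )
    scalars.to_csv(out / "country_scalars.csv", index=False)

    coverage = pd.concat(
        [
            p.baseline_coverage.rename("coverage").rename_axis("intervention_id").reset_index().assign(country_id=p.country_id)
            for p in profiles
        ],
        ignore_index=True,
    )
    coverage.to_csv(out / "baseline_coverage.csv", index=False)

    mort = pd.concat(
        [p.mortality_rate.assign(country_id=p.country_id) for p in profiles], ignore_index=True
    )
    mort.to_csv(out / "mortality_rates.csv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest or {}, fh, indent=2, sort_keys=True)
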