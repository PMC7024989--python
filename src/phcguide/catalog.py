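"""Intervention catalog and the three nested PHC measures.

Primary health care (PHC) is operationalised here as three nested
measures of scope.  Measure 1 covers preventive/public-health
interventions and general outpatient care with a partial share of
system support; measure 2 adds general inpatient care (normal
delivery, basic emergency obstetric care) and full health-sector
system support; measure 3 further adds cross-sectoral investments
(water and sanitation, food safety, air quality) and census/civil
registry information systems.

Each measure carries the allocation shares applied to shared
health-system costs: hospital infrastructure shares (33%/3% of
district/provincial hospital costs for the outpatient-only measure,
rising to 81%/27% once general inpatient care is included),
governance and financing shares (80% vs 100%), and scope switches
for health information systems, emergency preparedness and
conditional cash transfers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import pandas as pd

__all__ = [
    "Platform",
    "CauseGroup",
    "HisScope",
    "EmergencyScope",
    "CashTransferScope",
    "Intervention",
    "MeasureSpec",
    "MEASURES",
    "interventions_in_measure",
    "validate_catalog",
    "catalog_to_frame",
    "catalog_from_frame",
]


class Platform(str, Enum):
    """Service-delivery platform an intervention is delivered through."""

    POLICY_POPULATION = "policy/population"
    OUTREACH = "outreach"
    FIRST_LEVEL_CLINICAL = "first-level clinical"
    FIRST_LEVEL_AND_ABOVE = "first-level and above"
    CROSS_SECTORAL = "cross-sectoral"


class CauseGroup(str, Enum):
    """Cause-of-death group an intervention acts on."""

    MATERNAL = "maternal"
    NEONATAL = "neonatal"
    POST_NEONATAL_CHILD = "post-neonatal/child"
    STILLBIRTH = "stillbirth"
    NCD = "NCD"
    CANCER = "cancer"
    TB = "TB"
    HIV = "HIV"
    NTD = "NTD"
    OTHER = "other"


class HisScope(str, Enum):
    FACILITY_ONLY = "facility_only"
    FULL_SECTOR = "full_sector"
    FULL_SECTOR_PLUS_CENSUS = "full_sector_plus_census"


class EmergencyScope(str, Enum):
    LAB_SHARE_ONLY = "lab_share_only"
    FULL_PREPAREDNESS = "full_preparedness"


class CashTransferScope(str, Enum):
    NONE = "none"
    BIRTH_ONLY = "birth_only"
    GENERAL = "general"


@dataclass(frozen=True)
class Intervention:
    """One essential health service with its costing and impact parameters.

    ``effectiveness`` and ``cause_group`` are declared stand-ins for the
    disease-specific impact models of the original projection tool: the
    fraction of deaths from the addressed cause averted at full coverage.
    They are user-overridable and documented as synthetic.
    """

    intervention_id: str
    name: str
    platform: Platform
    in_m1: bool
    in_m2: bool
    in_m3: bool
    target_pop_fraction: float
    in_need_fraction: float
    units_per_case: float
    commodity_price: float  # US$2014 per unit, reference price
    visits_per_case: float
    minutes_per_visit: float
    capital_share: float
    effectiveness: float
    cause_group: CauseGroup

    def in_measure(self, measure_id: str) -> bool:
        return {"m1": self.in_m1, "m2": self.in_m2, "m3": self.in_m3}[measure_id]


@dataclass(frozen=True)
class MeasureSpec:
    """Allocation rules of one PHC measure over shared system costs."""

    measure_id: str
    district_hospital_share: float
    provincial_hospital_share: float
    health_centre_share: float
    governance_share: float
    financing_share: float
    his_scope: HisScope
    emergency_scope: EmergencyScope
    cash_transfer_scope: CashTransferScope
    includes_cross_sectoral: bool

    def __post_init__(self) -> None:
        for name in (
            "district_hospital_share",
            "provincial_hospital_share",
            "health_centre_share",
            "governance_share",
            "financing_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def with_overrides(self, **kwargs) -> "MeasureSpec":
        return replace(self, **kwargs)


#: Built-in measure definitions.  Hospital infrastructure shares come from
#: national-health-accounts data on non-specialised care; governance and
#: financing are 80% under the outpatient-only measure and full otherwise.
MEASURES: dict[str, MeasureSpec] = {
    "m1": MeasureSpec(
        measure_id="m1",
        district_hospital_share=0.33,
        provincial_hospital_share=0.03,
        health_centre_share=1.0,
        governance_share=0.80,
        financing_share=0.80,
        his_scope=HisScope.FACILITY_ONLY,
        emergency_scope=EmergencyScope.LAB_SHARE_ONLY,
        cash_transfer_scope=CashTransferScope.NONE,
        includes_cross_sectoral=False,
    ),
    "m2": MeasureSpec(
        measure_id="m2",
        district_hospital_share=0.81,
        provincial_hospital_share=0.27,
        health_centre_share=1.0,
        governance_share=1.0,
        financing_share=1.0,
        his_scope=HisScope.FULL_SECTOR,
        emergency_scope=EmergencyScope.FULL_PREPAREDNESS,
        cash_transfer_scope=CashTransferScope.BIRTH_ONLY,
        includes_cross_sectoral=False,
    ),
    "m3": MeasureSpec(
        measure_id="m3",
        district_hospital_share=0.81,
        provincial_hospital_share=0.27,
        health_centre_share=1.0,
        governance_share=1.0,
        financing_share=1.0,
        his_scope=HisScope.FULL_SECTOR_PLUS_CENSUS,
        emergency_scope=EmergencyScope.FULL_PREPAREDNESS,
        cash_transfer_scope=CashTransferScope.GENERAL,
        includes_cross_sectoral=True,
    ),
}


def interventions_in_measure(
    catalog: Iterable[Intervention], measure: MeasureSpec | str
) -> list[Intervention]:
    """Subset of the catalog flagged for a measure.

    Because membership is nested, the result for m1 is a subset of the
    result for m2, which is a subset of the result for m3.
    """
    measure_id = measure if isinstance(measure, str) else measure.measure_id
    if measure_id not in ("m1", "m2", "m3"):
        raise ValueError(f"unknown measure id: {measure_id!r}")
    return [iv for iv in catalog if iv.in_measure(measure_id)]


_FRACTION_FIELDS = (
    "target_pop_fraction",
    "in_need_fraction",
    "capital_share",
    "effectiveness",
)
_NONNEG_FIELDS = (
    "units_per_case",
    "commodity_price",
    "visits_per_case",
    "minutes_per_visit",
)


def validate_catalog(catalog: Iterable[Intervention]) -> list[str]:
    """Report (never raise) every invariant violation in a catalog.

    Returns an empty list iff every intervention satisfies the range
    and measure-nesting invariants; each violation names the
    intervention and the offending field.
    """
    violations: list[str] = []
    for iv in catalog:
        for f in _FRACTION_FIELDS:
            v = getattr(iv, f)
            if not 0.0 <= v <= 1.0:
                violations.append(f"{iv.intervention_id}: {f}={v} outside [0,1]")
        for f in _NONNEG_FIELDS:
            v = getattr(iv, f)
            if v < 0:
                violations.append(f"{iv.intervention_id}: {f}={v} negative")
        if iv.in_m1 and not (iv.in_m2 and iv.in_m3):
            violations.append(
                f"{iv.intervention_id}: in_m1 without in_m2/in_m3 (nesting)"
            )
        if iv.in_m2 and not iv.in_m3:
            violations.append(f"{iv.intervention_id}: in_m2 without in_m3 (nesting)")
    return violations


def catalog_to_frame(catalog: Iterable[Intervention]) -> pd.DataFrame:
    """Tidy one-row-per-intervention table (round-trips with
    :func:`catalog_from_frame`)."""
    rows = []
    for iv in catalog:
        d = iv.__dict__.copy()
        d["platform"] = iv.platform.value
        d["cause_group"] = iv.cause_group.value
        rows.append(d)
    return pd.DataFrame(rows)


def catalog_from_frame(frame: pd.DataFrame) -> list[Intervention]:
    out = []
    for _, row in frame.iterrows():
        d = row.to_dict()
        d["platform"] = Platform(d["platform"])
        d["cause_group"] = CauseGroup(d["cause_group"])
        d["in_m1"], d["in_m2"], d["in_m3"] = (
            bool(d["in_m1"]),
            bool(d["in_m2"]),
            bool(d["in_m3"]),
        )
        out.append(Intervention(**d))
    return out
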