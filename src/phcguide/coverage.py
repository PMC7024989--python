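"""Coverage scale-up trajectories and the flatline counterfactual.

Countries are assumed to expand intervention coverage at a pace set by
the maturity of their health system: weaker systems reach lower 2030
targets.  Little progress is assumed during 2015-2019, so the
trajectory holds the baseline through 2019 and then rises linearly to
the maturity-specific target in 2030.  The counterfactual holds
coverage flat at its 2015 baseline throughout ("flatline").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import YEARS

__all__ = ["MATURITY_TARGETS", "CoverageTrajectory", "build_trajectory", "flatline"]

#: Default 2030 coverage targets by system maturity.  The source model
#: differentiates speed by maturity without publishing the mapping;
#: these are config-exposed defaults.
MATURITY_TARGETS: dict[str, float] = {
    "conflict": 0.70,
    "vulnerable": 0.80,
    "hs1": 0.85,
    "hs2": 0.90,
    "hs3": 0.95,
}

_SCALE_UP_START = 2019


@dataclass(frozen=True)
class CoverageTrajectory:
    """Per-intervention coverage by calendar year 2015-2030."""

    values: np.ndarray  # aligned with YEARS
    counterfactual: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(YEARS),):
            raise ValueError(f"trajectory must have {len(YEARS)} annual values")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("coverage values must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def at(self, year: int) -> float:
        return float(self.values[YEARS.index(year)])


def build_trajectory(
    baseline: float,
    maturity: str,
    start_year: int = _SCALE_UP_START,
    end_year: int = 2030,
    target: float | None = None,
) -> CoverageTrajectory:
    """Linear scale-up from the baseline to the maturity target.

    Coverage equals ``baseline`` through ``start_year`` (limited
    2015-19 progress) and rises linearly to the target in
    ``end_year``.  Coverage is never scaled *down*: a baseline already
    at or above the target stays flat.
    """
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline must be in [0,1], got {baseline}")
    if target is None:
        try:
            target = MATURITY_TARGETS[maturity]
        except KeyError:
            raise ValueError(f"unknown maturity category: {maturity!r}") from None
    if baseline >= target:
        return CoverageTrajectory(np.full(len(YEARS), baseline))
    years = np.array(YEARS, dtype=float)
    frac = np.clip((years - start_year) / (end_year - start_year), 0.0, 1.0)
    return CoverageTrajectory(baseline + frac * (target - baseline))


def flatline(baseline: float) -> CoverageTrajectory:
    """Counterfactual: coverage unchanged at the 2015 baseline."""
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline must be in [0,1], got {baseline}")
    return CoverageTrajectory(np.full(len(YEARS), baseline), counterfactual=True)
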