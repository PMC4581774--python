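"""Per-parcel and per-network cost schedules.

Two acquisition strategies are costed:

* fee-simple purchase: the assessed value plus a fractional stewardship
  endowment added at acquisition;
* conservation easement: a one-time setup cost (fixed legal/financial/
  registration/endowment components plus three size-scaled curves) and a
  flat recurring annual cost for monitoring and staff time.

All monetary quantities are present-day CAD carried as exact floats; no
rounding happens inside the model (reports round at presentation time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "CostCurve",
    "EasementCostSchedule",
    "PurchaseCostModel",
    "purchase_cost",
    "variable_cost",
    "easement_setup_cost",
    "easement_recurring_annual",
]


@dataclass(frozen=True)
class CostCurve:
    """A saturating size-scaled cost: ``max(minimum, intercept + slope * ln(acres))``.

    Parameters
    ----------
    intercept : float
        Cost at 1 acre before the floor is applied, CAD.
    slope : float
        CAD per natural-log acre.
    minimum : float
        Floor below which the evaluated cost cannot fall, CAD.
    """

    intercept: float
    slope: float
    minimum: float

    def __post_init__(self) -> None:
        if self.minimum < 0:
            raise ConfigurationError("CostCurve.minimum must be non-negative")
        for name in ("intercept", "slope", "minimum"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"CostCurve.{name} must be finite")

    def __call__(self, area_acres: float) -> float:
        return variable_cost(self, area_acres)


@dataclass(frozen=True)
class EasementCostSchedule:
    """Easement transaction and stewardship cost constants (CAD).

    Defaults are the land-trust estimates used throughout: five fixed
    components (landowner legal, landowner financial advice, registration,
    stewardship endowment, holder legal), three size-scaled curves
    (ecological baseline, appraisal, land survey), and two recurring annual
    items (monitoring, staff time for landowner requests).
    """

    fixed_landowner_legal: float = 300.0
    fixed_landowner_financial: float = 300.0
    fixed_registration: float = 200.0
    fixed_endowment: float = 10_000.0
    fixed_holder_legal: float = 4_000.0
    curve_ecological_baseline: CostCurve = field(
        default_factory=lambda: CostCurve(2_185.0, 1_957.0, 1_000.0)
    )
    curve_appraisal: CostCurve = field(
        default_factory=lambda: CostCurve(0.0, 1_957.0, 1_500.0)
    )
    curve_land_survey: CostCurve = field(
        default_factory=lambda: CostCurve(300.0, 1_957.0, 1_000.0)
    )
    recurring_monitoring: float = 758.0
    recurring_staff: float = 151.6

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, CostCurve):
                continue
            if not math.isfinite(value) or value < 0:
                raise ConfigurationError(
                    f"EasementCostSchedule.{f.name} must be finite and non-negative"
                )

    @property
    def fixed_total(self) -> float:
        """Sum of the five fixed setup components (14,800 CAD with defaults)."""
        return (
            self.fixed_landowner_legal
            + self.fixed_landowner_financial
            + self.fixed_registration
            + self.fixed_endowment
            + self.fixed_holder_legal
        )


@dataclass(frozen=True)
class PurchaseCostModel:
    """Fee-simple purchase cost model: assessed value plus a trust-fund add-on."""

    trust_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not math.isfinite(self.trust_fraction) or self.trust_fraction < 0:
            raise ConfigurationError("trust_fraction must be finite and >= 0")


def purchase_cost(parcel, model: PurchaseCostModel | None = None) -> float:
    """Purchase cost of one parcel: ``assessed_value * (1 + trust_fraction)``.

    ``parcel`` may be anything exposing ``assessed_value``.
    """
    if model is None:
        model = PurchaseCostModel()
    return parcel.assessed_value * (1.0 + model.trust_fraction)


def variable_cost(curve: CostCurve, area_acres) -> float:
    """Evaluate a size-scaled cost curve, clamped from below at its minimum.

    Accepts a scalar or a numpy array of areas (all strictly positive).
    """
    area = np.asarray(area_acres, dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area <= 0):
        raise InputError("area_acres must be finite and > 0")
    raw = curve.intercept + curve.slope * np.log(area)
    clamped = np.maximum(curve.minimum, raw)
    return float(clamped) if np.isscalar(area_acres) else clamped


def easement_setup_cost(area_acres, schedule: EasementCostSchedule | None = None):
    """One-time easement setup cost for a parcel of the given area.

    The sum of all five fixed components and the three size-scaled curves.
    Accepts a scalar or array of areas.
    """
    if schedule is None:
        schedule = EasementCostSchedule()
    total = (
        schedule.fixed_total
        + variable_cost(schedule.curve_ecological_baseline, area_acres)
        + variable_cost(schedule.curve_appraisal, area_acres)
        + variable_cost(schedule.curve_land_survey, area_acres)
    )
    return total


def easement_recurring_annual(schedule: EasementCostSchedule | None = None) -> float:
    """Recurring annual cost per easement (area-independent): monitoring + staff."""
    if schedule is None:
        schedule = EasementCostSchedule()
    return schedule.recurring_monitoring + schedule.recurring_staff
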