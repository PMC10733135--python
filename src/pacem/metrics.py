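"""Per-event exposure metrics.

Two exposure metrics are supported:

*Dermal load* (ug substance per cm2 of exposed skin), the metric used in
skin-sensitisation risk assessment::

    load = amount_g * 1e6 * concentration * retention / surface_area_cm2

with a retention factor in [0, 1] expressing how much of the applied
product remains on the skin (e.g. after rinsing).  Loads are tracked per
body part (trunk, head, arms, hands, legs, feet); products applied to the
same part on the same day add up, and the body part with the highest daily
load is the reported exposure.

*Systemic dose* (mg substance per kg body weight per day)::

    dose = amount_g * 1e3 * concentration * sum_route(EF * fabs) / body_weight_kg

where the exposure fraction EF of a route is the fraction of the substance
used in an event that the user is exposed to via that route, and fabs the
fraction of that exposure that is systemically absorbed.

A small well-mixed-room helper derives an inhalation exposure fraction
from an event scenario: a mass A released instantly into a ventilated room
and inhaled over the stay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .survey import BODY_PARTS

__all__ = [
    "ROUTES",
    "DEFAULT_SURFACE_AREA_CM2",
    "DEFAULT_RETENTION",
    "MetricsError",
    "BodyPartParams",
    "RouteParams",
    "RoomScenario",
    "dermal_load",
    "max_body_part_load",
    "systemic_dose",
    "room_inhaled_dose",
    "room_exposure_fraction",
]

ROUTES = ("oral", "inhalation", "dermal")

#: Default adult body-part surface areas (cm2).  These are configuration
#: defaults, overridable per assessment.
DEFAULT_SURFACE_AREA_CM2: dict[str, float] = {
    "trunk": 5690.0,
    "head": 1305.0,
    "arms": 2282.0,
    "hands": 860.0,
    "legs": 5528.0,
    "feet": 1310.0,
}

#: Default retention factors by product rinse class: leave-on products
#: stay on the skin; rinse-off products and hand-contact cleaning products
#: leave about 1% behind.
DEFAULT_RETENTION: dict[str, float] = {
    "leave_on": 1.0,
    "rinse_off": 0.01,
    "hcp_hand_contact": 0.01,
}


class MetricsError(ValueError):
    """Invalid exposure-metric parameters."""


@dataclass(frozen=True)
class BodyPartParams:
    body_part: str
    surface_area: float  # cm2
    retention: float

    def __post_init__(self) -> None:
        if self.body_part not in BODY_PARTS:
            raise MetricsError(f"unknown body part {self.body_part!r}")
        if self.surface_area <= 0:
            raise MetricsError("surface_area must be > 0")
        if not 0 <= self.retention <= 1:
            raise MetricsError("retention must be in [0, 1]")


@dataclass(frozen=True)
class RouteParams:
    route: str
    exposure_fraction: float
    absorption_fraction: float

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise MetricsError(f"unknown route {self.route!r}")
        if not 0 <= self.exposure_fraction <= 1:
            raise MetricsError("exposure_fraction must be in [0, 1]")
        if not 0 <= self.absorption_fraction <= 1:
            raise MetricsError("absorption_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RoomScenario:
    """Instant release of mass A (g) into a well-mixed ventilated room.

    V: room volume (m3); q: ventilation rate (air changes/h); t: duration
    of stay (h); inhalation_rate: breathing rate (m3/h).
    """

    A: float
    V: float
    q: float
    t: float
    inhalation_rate: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise MetricsError("released mass A must be >= 0")
        for name in ("V", "q", "t", "inhalation_rate"):
            if getattr(self, name) <= 0:
                raise MetricsError(f"{name} must be > 0")


def dermal_load(amount, concentration, retention, surface_area) -> np.ndarray | float:
    """Dermal load in ug/cm2 for an applied amount (g) of product.

    Vectorised over numpy inputs.
    """
    surface_area = np.asarray(surface_area, dtype=float)
    if (surface_area <= 0).any():
        raise MetricsError("surface_area must be > 0")
    out = np.asarray(amount, dtype=float) * 1e6 * np.asarray(concentration) \
        * np.asarray(retention) / surface_area
    return out if out.ndim else float(out)


def max_body_part_load(loads: Mapping[str, np.ndarray | float]) -> np.ndarray | float:
    """Exposure measure from per-body-part daily loads: the maximum over
    body parts (loads must already be summed over products within a part)."""
    if not loads:
        raise MetricsError("no body parts present")
    stacked = np.stack([np.asarray(v, dtype=float) for v in loads.values()])
    out = stacked.max(axis=0)
    return out if out.ndim else float(out)


def systemic_dose(
    amount, concentration, routes: Sequence[RouteParams], body_weight
) -> np.ndarray | float:
    """Systemic dose in mg per kg body weight for an amount (g) used."""
    if not routes:
        raise MetricsError("at least one exposure route required")
    body_weight = np.asarray(body_weight, dtype=float)
    if (body_weight <= 0).any():
        raise MetricsError("body_weight must be > 0")
    factor = sum(r.exposure_fraction * r.absorption_fraction for r in routes)
    out = np.asarray(amount, dtype=float) * 1e3 * np.asarray(concentration) \
        * factor / body_weight
    return out if out.ndim else float(out)


def room_inhaled_dose(s: RoomScenario) -> float:
    """Mass (g) inhaled in the well-mixed-room scenario:

        D = A * (1 - exp(-q*t)) / (q*V) * R_inhale
    """
    denom = s.q * s.V
    if denom == 0:
        raise MetricsError("q*V must be > 0")
    return s.A * (1.0 - math.exp(-s.q * s.t)) / denom * s.inhalation_rate


def room_exposure_fraction(s: RoomScenario) -> float:
    """Inhalation exposure fraction for the scenario: inhaled dose / amount
    used.  Independent of A (exposure is assumed linear in amount used)."""
    if s.A == 0:
        raise MetricsError("exposure fraction undefined for A = 0")
    ef = room_inhaled_dose(s) / s.A
    if ef > 1:
        warnings.warn(f"exposure fraction {ef:.3g} > 1; check scenario", stacklevel=2)
    return ef
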