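"""Aerodynamic power partition and flight-energetics ratio arithmetic.

The classical partition splits aerodynamic power into a parasite term
(body drag, ~U^3), an induced term (~1/U) and an approximately constant
profile term. The change operations are pure ratio arithmetic on
dimensionless power/frequency/speed ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

G_STANDARD = 9.80665  # m s-2

__all__ = [
    "PowerModelParams",
    "PowerComponents",
    "parasite_power_change",
    "classical_power",
    "minimum_power_speed",
    "work_per_beat_change",
    "cost_of_transport_change",
    "wingbeat_budget",
]


@dataclass(frozen=True)
class PowerModelParams:
    """Parameters of the classical fixed-wing power partition.

    Body frontal area defaults to the allometric 0.00813 * m^0.666 (m in kg);
    profile power defaults to (8.4 / aspect_ratio) times the absolute minimum
    of the parasite+induced curve.
    """

    mass_kg: float
    rho: float = 1.225  # kg m-3
    span_m: float = 0.67
    aspect_ratio: float = 6.9
    cd_body: float = 0.1
    k_induced: float = 1.2
    body_area_m2: Optional[float] = None  # default allometric if None
    profile_power_w: Optional[float] = None  # default 8.4/AR * P_am if None

    def __post_init__(self) -> None:
        for name in ("mass_kg", "rho", "span_m", "aspect_ratio", "cd_body", "k_induced"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def frontal_area_m2(self) -> float:
        if self.body_area_m2 is not None:
            if self.body_area_m2 <= 0:
                raise ValueError("body_area_m2 must be positive")
            return self.body_area_m2
        return 0.00813 * self.mass_kg ** 0.666

    @property
    def disk_area_m2(self) -> float:
        return math.pi * self.span_m**2 / 4.0


@dataclass(frozen=True)
class PowerComponents:
    parasite_w: float
    induced_w: float
    profile_w: float

    @property
    def total_w(self) -> float:
        return self.parasite_w + self.induced_w + self.profile_w


def _coeffs(params: PowerModelParams) -> tuple[float, float]:
    """(c3, c1) such that P_par = c3 U^3 and P_ind = c1 / U."""
    c3 = 0.5 * params.rho * params.frontal_area_m2 * params.cd_body
    weight = params.mass_kg * G_STANDARD
    c1 = params.k_induced * weight**2 / (2.0 * params.rho * params.disk_area_m2)
    return c3, c1


def minimum_power_speed(params: PowerModelParams) -> float:
    """Analytic stationary point of the parasite+induced curve."""
    c3, c1 = _coeffs(params)
    return (c1 / (3.0 * c3)) ** 0.25


def _default_profile_power(params: PowerModelParams) -> float:
    c3, c1 = _coeffs(params)
    ump = minimum_power_speed(params)
    p_am = c3 * ump**3 + c1 / ump
    return (8.4 / params.aspect_ratio) * p_am


def classical_power(u_ms: float, params: PowerModelParams) -> PowerComponents:
    """Classical three-component aerodynamic power at airspeed u_ms (W)."""
    if u_ms <= 4.0:
        raise ValueError("airspeed must exceed the 4 m/s stall proxy")
    c3, c1 = _coeffs(params)
    profile = (
        params.profile_power_w
        if params.profile_power_w is not None
        else _default_profile_power(params)
    )
    if profile < 0:
        raise ValueError("profile power must be non-negative")
    return PowerComponents(
        parasite_w=c3 * u_ms**3, induced_w=c1 / u_ms, profile_w=profile
    )


def parasite_power_change(speed_ratio: float) -> float:
    """Percent change in parasite power for a given airspeed ratio (U^3 law)."""
    if speed_ratio <= 0:
        raise ValueError("speed_ratio must be positive")
    return (speed_ratio**3 - 1.0) * 100.0


def work_per_beat_change(power_ratio: float, freq_ratio: float) -> float:
    """Percent change in mechanical work per wingbeat implied by total-power
    and wingbeat-frequency ratios."""
    if power_ratio <= 0 or freq_ratio <= 0:
        raise ValueError("ratios must be positive")
    return (power_ratio / freq_ratio - 1.0) * 100.0


def cost_of_transport_change(power_ratio: float, speed_ratio: float) -> float:
    """Percent change in energy per unit distance (power/speed ratio)."""
    if power_ratio <= 0 or speed_ratio <= 0:
        raise ValueError("ratios must be positive")
    return (power_ratio / speed_ratio - 1.0) * 100.0


def wingbeat_budget(
    straight_dist_m: float, accuracy: float, airspeed_ms: float, freq_hz: float
) -> float:
    """Total wingbeats to cover a straight-line distance given route accuracy,
    airspeed and wingbeat frequency.

    Path length = straight distance / accuracy; duration = path / airspeed;
    beats = duration * frequency.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must lie in (0, 1]")
    if straight_dist_m <= 0 or airspeed_ms <= 0 or freq_hz <= 0:
        raise ValueError("distance, airspeed and frequency must be positive")
    path_m = straight_dist_m / accuracy
    return path_m / airspeed_ms * freq_hz
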