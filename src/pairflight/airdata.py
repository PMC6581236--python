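"""Wind-triangle decomposition and humid air density.

Wind support / crosswind / airspeed follow the standard track-relative
decomposition of the wind vector; air density follows the ideal-gas mixture
of dry air and water vapour, with saturation vapour pressure from the
Arden–Buck equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

R_DRY = 287.05  # J kg-1 K-1
R_VAPOUR = 461.495  # J kg-1 K-1
KELVIN = 273.15

__all__ = [
    "R_DRY",
    "R_VAPOUR",
    "WeatherRecord",
    "AtmosphereState",
    "buck_psat",
    "humid_air_density",
    "atmosphere_state",
    "wind_triangle",
]


@dataclass(frozen=True)
class WeatherRecord:
    """One weather observation.

    wind_dir_deg is meteorological: the direction the wind blows FROM.
    """

    wind_speed_ms: float
    wind_dir_deg: float
    temp_c: float
    humidity_pct: float
    pressure_hpa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.humidity_pct <= 100.0:
            raise ValueError("humidity_pct must lie in [0, 100]")
        if self.pressure_hpa <= 0:
            raise ValueError("pressure must be positive")
        if self.wind_speed_ms < 0:
            raise ValueError("wind speed must be non-negative")


@dataclass(frozen=True)
class AtmosphereState:
    p_sat_pa: float
    p_vapour_pa: float
    p_dry_pa: float
    temp_k: float
    rho_air: float


def buck_psat(temp_c: float) -> float:
    """Saturation vapour pressure over water (Pa) via the Arden–Buck fit.

    The fit constant 0.61121 is in kPa; the result is converted to Pa
    (611.21 Pa at 0 degC).
    """
    if not -40.0 < temp_c < 50.0:
        raise ValueError("temperature outside the fit's validity (-40, 50) degC")
    kpa = 0.61121 * math.exp(
        (18.678 - temp_c / 234.5) * (temp_c / (257.14 + temp_c))
    )
    return kpa * 1000.0


def atmosphere_state(weather: WeatherRecord) -> AtmosphereState:
    """Full dry-air/vapour partition for a weather record."""
    p_pa = weather.pressure_hpa * 100.0
    p_sat = buck_psat(weather.temp_c)
    p_v = (weather.humidity_pct / 100.0) * p_sat
    if p_v > p_pa:
        raise ValueError("vapour pressure exceeds total pressure")
    p_d = p_pa - p_v
    t_k = weather.temp_c + KELVIN
    rho = p_d / (R_DRY * t_k) + p_v / (R_VAPOUR * t_k)
    return AtmosphereState(
        p_sat_pa=p_sat, p_vapour_pa=p_v, p_dry_pa=p_d, temp_k=t_k, rho_air=rho
    )


def humid_air_density(weather: WeatherRecord) -> float:
    """Humid air density (kg m-3) from pressure, temperature and humidity."""
    return atmosphere_state(weather).rho_air


def wind_triangle(ground_speed_ms, heading_deg, weather: WeatherRecord):
    """Decompose ground motion into (wind_support_ms, crosswind_ms, airspeed_ms).

    The wind vector points in the direction the air moves toward
    (wind_dir_deg + 180). Wind support is its signed projection on the track
    direction; crosswind is the magnitude of the perpendicular component;
    airspeed is |ground velocity - wind velocity|. Accepts scalars or arrays.
    """
    gs = np.asarray(ground_speed_ms, dtype=float)
    if np.any(gs < 0):
        raise ValueError("ground speed must be non-negative")
    if weather.wind_speed_ms < 0:
        raise ValueError("wind speed must be non-negative")
    hdg = np.radians(np.asarray(heading_deg, dtype=float))
    wind_to = math.radians(weather.wind_dir_deg + 180.0)

    # East/north components.
    g_e, g_n = gs * np.sin(hdg), gs * np.cos(hdg)
    w_e = weather.wind_speed_ms * math.sin(wind_to)
    w_n = weather.wind_speed_ms * math.cos(wind_to)

    track_e, track_n = np.sin(hdg), np.cos(hdg)
    support = w_e * track_e + w_n * track_n
    cross = np.abs(w_e * track_n - w_n * track_e)
    a_e, a_n = g_e - w_e, g_n - w_n
    airspeed = np.hypot(a_e, a_n)
    if support.ndim == 0:
        return float(support), float(cross), float(airspeed)
    return support, cross, airspeed
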