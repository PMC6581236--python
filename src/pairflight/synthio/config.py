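"""Configuration and domain records for the synthetic generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

# Release site and home loft used throughout as defaults (decimal degrees).
RELEASE_SITE = (51.0 + 47.0 / 60.0 + 48.1 / 3600.0, -(1.0 + 25.0 / 60.0 + 3.3 / 3600.0))
HOME_LOFT = (51.0 + 46.0 / 60.0 + 58.2 / 3600.0, -(1.0 + 19.0 / 60.0 + 2.7 / 3600.0))


@dataclass(frozen=True)
class BirdRecord:
    """One bird: identity, morphometrics and its solo wingbeat baseline."""

    bird_id: str
    tarsus_mm: float
    mass_g: float
    solo_freq_hz: float

    def __post_init__(self) -> None:
        if self.tarsus_mm <= 0 or self.mass_g <= 0:
            raise ValueError("tarsus and mass must be positive")
        if not 2.0 < self.solo_freq_hz < 12.0:
            raise ValueError("solo_freq_hz must lie in (2, 12) Hz")


@dataclass(frozen=True)
class PopulationConfig:
    """Normal-law moments for the bird registry."""

    freq_mean_hz: float = 5.48
    freq_sd_hz: float = 0.19
    tarsus_mean_mm: float = 33.5
    tarsus_sd_mm: float = 1.5
    mass_mean_g: float = 450.0
    mass_sd_g: float = 35.0

    def __post_init__(self) -> None:
        for name in ("freq_sd_hz", "tarsus_sd_mm", "mass_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """Generative ground truth for a synthetic dataset."""

    delta0_hz: float = 1.0  # pairing effect on wingbeat frequency
    delta1_hz_per_mm: float = 0.0  # tarsus-difference effect
    spacing_slope_hz_per_m: float = -0.011  # per-metre effect within a pair
    accuracy_solo: float = 0.86
    accuracy_pair: float = 0.92
    pp_accel_g: float = 2.5
    upstroke_frac: float = 133.8 / 182.5  # min->max share of the solo cycle
    eta1: float = 0.0  # mixing-weight sigmoid intercept (omega = 0.5 at 0)
    eta_slope_per_mm: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    residual_sd_hz: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy_solo", "accuracy_pair"):
            v = getattr(self, name)
            if not -1.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (-1, 1]")
        if not 0.0 < self.upstroke_frac < 1.0:
            raise ValueError("upstroke_frac must lie in (0, 1)")
        if self.residual_sd_hz < 0:
            raise ValueError("residual_sd_hz must be non-negative")
        if self.pp_accel_g <= 0:
            raise ValueError("pp_accel_g must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FlightPlan:
    """One release: which bird(s), phase/condition, and the weather."""

    flight_id: str
    phase: int
    condition: str  # solo | pair
    bird_ids: tuple
    pair_id: Optional[str] = None
    release_epoch: float = 0.0
    wind_speed_ms: float = 0.0
    wind_dir_deg: float = 0.0
    temp_c: float = 15.0
    humidity_pct: float = 60.0
    pressure_hpa: float = 1013.25

    def __post_init__(self) -> None:
        if self.phase not in (1, 2, 3, 4):
            raise ValueError("phase must be one of 1-4")
        if self.condition not in ("solo", "pair"):
            raise ValueError("condition must be 'solo' or 'pair'")
        ids = tuple(self.bird_ids)
        object.__setattr__(self, "bird_ids", ids)
        if (self.condition == "pair") != (len(ids) == 2):
            raise ValueError("condition is 'pair' iff exactly two bird_ids")
        if self.condition == "solo" and len(ids) != 1:
            raise ValueError("solo flights carry exactly one bird")


@dataclass(frozen=True)
class SimConfig:
    """Track and accelerometer simulation constants."""

    # Track geometry
    release_latlon: tuple = RELEASE_SITE
    loft_latlon: tuple = HOME_LOFT
    airspeed_ms: float = 18.0
    fix_rate_hz: float = 5.0
    gps_noise_sd_m: float = 1.5
    stop_radius_m: float = 50.0
    max_steps_factor: float = 5.0
    # Paired-offset process (mean-reverting)
    lead_mean_m: float = 11.0
    offset_ou_sd_m: float = 2.0
    offset_ou_tau_s: float = 30.0
    # Accelerometer
    accel_rate_hz: float = 200.0
    accel_duration_s: float = 60.0
    accel_noise_sd_g: float = 0.0
    lateral_noise_sd_g: float = 0.05
    down_ms: float = 48.7  # near-constant downstroke segment
    waveform: str = "two_segment"  # two_segment | sinusoid


@dataclass(frozen=True)
class ScenarioConfig:
    """Shape of the full study design."""

    n_birds: int = 20
    flights_per_phase: int = 6
    release_interval_s: float = 3600.0
    max_wind_ms: float = 7.0

    def __post_init__(self) -> None:
        if self.n_birds < 2 or self.n_birds % 2:
            raise ValueError("n_birds must be an even count >= 2")
        if self.flights_per_phase < 1:
            raise ValueError("flights_per_phase must be >= 1")
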