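"""Accelerometer waveform synthesis.

The dorsal channel is 1 g static plus a periodic dynamic wave. The default
waveform is a two-segment cosine: a falling half-cosine from the cycle
maximum to the minimum (the downstroke segment) followed by a rising
half-cosine back to the maximum (the upstroke segment). The segments can
have unequal durations, which is how stroke-phase asymmetry — and its
change under pairing — is encoded: pairing raises frequency by shortening
the upstroke segment while the downstroke stays near-constant.
"""

from __future__ import annotations

import zlib

import numpy as np

from ..kinematics import AccelTrace
from .config import BirdRecord, FlightPlan, SimConfig, TruthRecord

__all__ = ["two_segment_wave", "sinusoid_wave", "pair_frequency", "simulate_accel"]


def two_segment_wave(
    duration_s: float,
    freq_hz: float,
    pp_g: float,
    down_s: float,
    rate_hz: float,
) -> np.ndarray:
    """Two-segment cosine wave with peak-to-peak amplitude pp_g.

    Each cycle runs max -> min over down_s then min -> max over the
    remainder of the period; the segment durations sum to the period
    exactly. The wave starts at a maximum.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    period = 1.0 / freq_hz
    up_s = period - down_s
    if down_s <= 0 or up_s <= 0:
        raise ValueError("downstroke segment must lie strictly inside the period")
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    tau = np.mod(t, period)
    half = 0.5 * pp_g
    return np.where(
        tau < down_s,
        half * np.cos(np.pi * tau / down_s),
        -half * np.cos(np.pi * (tau - down_s) / up_s),
    )


def sinusoid_wave(
    duration_s: float, freq_hz: float, pp_g: float, rate_hz: float
) -> np.ndarray:
    """Pure cosine with peak-to-peak amplitude pp_g, starting at a maximum."""
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    return 0.5 * pp_g * np.cos(2.0 * np.pi * freq_hz * t)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _covariate_term(truth: TruthRecord, plan: FlightPlan) -> float:
    return sum(
        eff * float(getattr(plan, name, 0.0))
        for name, eff in truth.covariate_effects.items()
    )


def pair_frequency(
    bird: BirdRecord,
    partner: BirdRecord | None,
    truth: TruthRecord,
    plan: FlightPlan,
    spacing_m: float = 0.0,
) -> float:
    """Expected wingbeat frequency under the generative pairing model.

    Solo: the bird's own baseline plus covariate effects. Paired: a
    sigmoid-weighted average of both baselines plus the pairing offset, the
    tarsus-difference term and the per-metre spacing term.
    """
    gx = _covariate_term(truth, plan)
    if partner is None:
        return bird.solo_freq_hz + gx
    d_tarsus = abs(bird.tarsus_mm - partner.tarsus_mm)
    omega = _sigmoid(truth.eta1 + truth.eta_slope_per_mm * d_tarsus)
    return (
        omega * bird.solo_freq_hz
        + (1.0 - omega) * partner.solo_freq_hz
        + truth.delta0_hz
        + truth.delta1_hz_per_mm * d_tarsus
        + truth.spacing_slope_hz_per_m * spacing_m
        + gx
    )


def simulate_accel(
    plan: FlightPlan,
    birds: list[BirdRecord],
    truth: TruthRecord,
    seed: int,
    cfg: SimConfig | None = None,
    spacing_m: float | None = None,
) -> dict[str, AccelTrace]:
    """Simulate one 200 Hz tri-axial trace per bird on the plan.

    The realised per-flight frequency is the generative expectation plus
    normal noise (truth.residual_sd_hz). A paired bird's higher frequency is
    produced entirely by shortening the upstroke segment: the downstroke
    duration cfg.down_ms is held fixed.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng([seed, zlib.crc32(plan.flight_id.encode()), 1])
    if spacing_m is None:
        spacing_m = cfg.lead_mean_m if plan.condition == "pair" else 0.0

    lookup = {b.bird_id: b for b in birds}
    traces: dict[str, AccelTrace] = {}
    for bird_id in plan.bird_ids:
        bird = lookup[bird_id]
        partner = None
        if plan.condition == "pair":
            other = [i for i in plan.bird_ids if i != bird_id][0]
            partner = lookup[other]
        freq = pair_frequency(bird, partner, truth, plan, spacing_m)
        freq += rng.normal(0.0, truth.residual_sd_hz)
        if freq <= 0:
            raise ValueError(f"non-positive wingbeat frequency for {bird_id}")
        n = int(round(cfg.accel_duration_s * cfg.accel_rate_hz))
        if cfg.waveform == "sinusoid":
            wave = sinusoid_wave(
                cfg.accel_duration_s, freq, truth.pp_accel_g, cfg.accel_rate_hz
            )
        else:
            wave = two_segment_wave(
                cfg.accel_duration_s,
                freq,
                truth.pp_accel_g,
                cfg.down_ms / 1000.0,
                cfg.accel_rate_hz,
            )
        az = 1.0 + wave
        if cfg.accel_noise_sd_g > 0:
            az = az + rng.normal(0.0, cfg.accel_noise_sd_g, size=n)
        lateral_sd = cfg.lateral_noise_sd_g
        ax = rng.normal(0.0, lateral_sd, size=n) if lateral_sd > 0 else np.zeros(n)
        ay = rng.normal(0.0, lateral_sd, size=n) if lateral_sd > 0 else np.zeros(n)
        traces[bird_id] = AccelTrace(
            t=np.arange(n) / cfg.accel_rate_hz,
            ax=ax,
            ay=ay,
            az=az,
            sample_rate_hz=cfg.accel_rate_hz,
            mount="dorsal",
        )
    return traces
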