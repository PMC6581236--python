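"""GPS track simulation with calibrated heading-error concentration.

Per fix the bird aims at the goal with an i.i.d. von Mises heading error
whose concentration kappa is chosen so that the expected cosine of the
error — the Bessel-function ratio I1(kappa)/I0(kappa) — equals the target
route accuracy. Ground velocity is the air velocity plus the wind vector.
Paired birds share one centroid heading process and ride mean-reverting
along-track/lateral offsets that keep their spacing small, with a fixed
mean lead making one bird the consistent leader.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from ..trackgeo import EARTH_RADIUS_M, GpsTrack
from .config import BirdRecord, FlightPlan, SimConfig, TruthRecord

__all__ = ["mean_cos_vonmises", "kappa_from_accuracy", "simulate_track"]


def mean_cos_vonmises(kappa: float) -> float:
    """E[cos(theta)] for theta ~ von Mises(0, kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_from_accuracy(accuracy: float) -> float:
    """Invert the Bessel ratio: concentration giving E[cos(error)] = accuracy."""
    if not 0.0 < accuracy < 1.0:
        raise ValueError("target accuracy must lie strictly in (0, 1)")
    return brentq(lambda k: mean_cos_vonmises(k) - accuracy, 1e-9, 1e7, xtol=1e-10)


def _latlon_to_en(lat, lon, origin):
    """Equirectangular east/north metres about an origin (small-area use)."""
    lat0 = math.radians(origin[0])
    east = np.radians(np.asarray(lon) - origin[1]) * math.cos(lat0) * EARTH_RADIUS_M
    north = np.radians(np.asarray(lat) - origin[0]) * EARTH_RADIUS_M
    return east, north


def _en_to_latlon(east, north, origin):
    lat0 = math.radians(origin[0])
    lat = origin[0] + np.degrees(np.asarray(north) / EARTH_RADIUS_M)
    lon = origin[1] + np.degrees(np.asarray(east) / (EARTH_RADIUS_M * math.cos(lat0)))
    return lat, lon


def _ou_path(rng, n, dt, mean, sd, tau):
    """Mean-reverting (Ornstein-Uhlenbeck) offset sampled at the fix rate."""
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    if tau <= 0:
        x[1:] = mean + sd * rng.standard_normal(n - 1)
        return x
    a = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(max(1.0 - a * a, 0.0))
    eps = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mean + a * (x[i - 1] - mean) + innov_sd * eps[i - 1]
    return x


def _simulate_centroid(rng, kappa, plan: FlightPlan, cfg: SimConfig):
    """Step a single heading process from release to loft in local metres.

    Returns (east, north, heading_rad) arrays; headings are per-step
    (length n-1).
    """
    origin = cfg.loft_latlon
    e0, n0 = _latlon_to_en(cfg.release_latlon[0], cfg.release_latlon[1], origin)
    e0, n0 = float(e0), float(n0)
    beeline = math.hypot(e0, n0)
    dt = 1.0 / cfg.fix_rate_hz
    step_air = cfg.airspeed_ms * dt
    max_steps = int(cfg.max_steps_factor * beeline / step_air) + 2

    wind_to = math.radians(plan.wind_dir_deg + 180.0)
    w_e = plan.wind_speed_ms * math.sin(wind_to) * dt
    w_n = plan.wind_speed_ms * math.cos(wind_to) * dt

    errors = rng.vonmises(0.0, kappa, size=max_steps)
    east = np.empty(max_steps + 1)
    north = np.empty(max_steps + 1)
    hdg = np.empty(max_steps)
    east[0], north[0] = e0, n0
    n_used = 0
    for i in range(max_steps):
        de, dn = -east[i], -north[i]  # toward the loft at the origin
        dist = math.hypot(de, dn)
        if dist < cfg.stop_radius_m:
            break
        theta = math.atan2(de, dn) + errors[i]  # azimuth convention
        hdg[i] = theta
        east[i + 1] = east[i] + step_air * math.sin(theta) + w_e
        north[i + 1] = north[i] + step_air * math.cos(theta) + w_n
        n_used = i + 1
    n_fix = n_used + 1
    return east[:n_fix], north[:n_fix], hdg[:n_used]


def _to_track(east, north, rng, plan, cfg, bird_id) -> GpsTrack:
    if cfg.gps_noise_sd_m > 0:
        east = east + rng.normal(0.0, cfg.gps_noise_sd_m, size=len(east))
        north = north + rng.normal(0.0, cfg.gps_noise_sd_m, size=len(north))
    lat, lon = _en_to_latlon(east, north, cfg.loft_latlon)
    t = np.arange(len(east)) / cfg.fix_rate_hz
    return GpsTrack(t=t, lat=lat, lon=lon, flight_id=plan.flight_id, bird_id=bird_id)


def simulate_track(
    plan: FlightPlan,
    birds: list[BirdRecord],
    truth: TruthRecord,
    seed: int,
    cfg: SimConfig | None = None,
) -> dict[str, GpsTrack]:
    """Simulate one 5 Hz GPS track per bird on the plan.

    Solo plans step a single heading process. Paired plans share a centroid
    process (concentration calibrated to truth.accuracy_pair) on which each
    bird rides an along-track/lateral mean-reverting offset; the first bird
    in the plan leads by cfg.lead_mean_m on average.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng([seed, zlib.crc32(plan.flight_id.encode())])
    target = truth.accuracy_pair if plan.condition == "pair" else truth.accuracy_solo
    kappa = kappa_from_accuracy(target)

    east, north, hdg = _simulate_centroid(rng, kappa, plan, cfg)
    if plan.condition == "solo":
        return {plan.bird_ids[0]: _to_track(east, north, rng, plan, cfg, plan.bird_ids[0])}

    n_fix = len(east)
    dt = 1.0 / cfg.fix_rate_hz
    # Offset frame: the slowly varying bearing-to-goal, not the noisy
    # per-step heading — a frame that jitters would shake the riders'
    # positions and corrupt their own route accuracy.
    h = np.arctan2(-east, -north)
    he, hn = np.sin(h), np.cos(h)

    tracks: dict[str, GpsTrack] = {}
    leads = (+0.5 * cfg.lead_mean_m, -0.5 * cfg.lead_mean_m)
    for bird_id, lead in zip(plan.bird_ids, leads):
        along = _ou_path(rng, n_fix, dt, lead, cfg.offset_ou_sd_m, cfg.offset_ou_tau_s)
        lateral = _ou_path(rng, n_fix, dt, 0.0, cfg.offset_ou_sd_m, cfg.offset_ou_tau_s)
        be = east + along * he + lateral * hn
        bn = north + along * hn - lateral * he
        tracks[bird_id] = _to_track(be, bn, rng, plan, cfg, bird_id)
    return tracks
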