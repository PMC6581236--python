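"""Direct generators for model-level data.

These bypass waveform/track synthesis and draw flight summaries or
wingbeat rows straight from the generative model — the fast path for
parameter-recovery studies where the signal-processing stages are not under
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BirdRecord, TruthRecord
from .waveforms import _sigmoid

__all__ = ["simulate_flight_summaries", "simulate_wingbeat_rows"]


def simulate_flight_summaries(
    birds: list[BirdRecord],
    truth: TruthRecord,
    *,
    n_solo: int = 12,
    n_pair: int = 12,
    seed: int = 0,
    response: str = "median_freq_hz",
    baselines: dict[str, float] | None = None,
    residual_sd: float | None = None,
) -> pd.DataFrame:
    """Per-flight median summaries drawn from the hierarchical model.

    Each bird gets n_solo solo rows (own baseline + noise) and n_pair paired
    rows (sigmoid-weighted baseline mixture + pairing and tarsus terms +
    noise), with partners rotating over the registry. Pass ``baselines`` to
    override the per-bird means (e.g. a route-accuracy response instead of
    wingbeat frequency).
    """
    if len(birds) < 2:
        raise ValueError("need at least 2 birds")
    rng = np.random.default_rng(seed)
    sd = truth.residual_sd_hz if residual_sd is None else residual_sd
    base = baselines or {b.bird_id: b.solo_freq_hz for b in birds}
    rows = []
    fid = 0
    for b in birds:
        for _ in range(n_solo):
            rows.append(
                {
                    "flight_id": f"F{fid:04d}",
                    "bird_id": b.bird_id,
                    "partner_id": "",
                    "is_pair": 0,
                    "tarsus_diff_mm": 0.0,
                    response: base[b.bird_id] + rng.normal(0.0, sd),
                }
            )
            fid += 1
    n_birds = len(birds)
    for bi, b in enumerate(birds):
        for k in range(n_pair):
            partner = birds[(bi + 1 + k % (n_birds - 1)) % n_birds]
            dt = abs(b.tarsus_mm - partner.tarsus_mm)
            omega = _sigmoid(truth.eta1 + truth.eta_slope_per_mm * dt)
            mean = (
                omega * base[b.bird_id]
                + (1.0 - omega) * base[partner.bird_id]
                + truth.delta0_hz
                + truth.delta1_hz_per_mm * dt
            )
            rows.append(
                {
                    "flight_id": f"F{fid:04d}",
                    "bird_id": b.bird_id,
                    "partner_id": partner.bird_id,
                    "is_pair": 1,
                    "tarsus_diff_mm": dt,
                    response: mean + rng.normal(0.0, sd),
                }
            )
            fid += 1
    return pd.DataFrame(rows)


def simulate_wingbeat_rows(
    *,
    n_pair_flights: int = 50,
    n_solo_flights: int = 50,
    beats_per_flight: int = 100,
    base_hz: float = 5.48,
    pair_intercept_hz: float = 1.21,
    spacing_slope_hz_per_m: float = -0.011,
    max_spacing_m: float = 50.0,
    flight_sd_hz: float = 0.1,
    residual_sd_hz: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Individual-wingbeat rows for the spacing model.

    Paired beats carry a spacing drawn uniformly on [0, max_spacing_m] and a
    frequency base + intercept + slope*spacing; every flight has a normal
    random effect of SD flight_sd_hz.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_solo_flights + n_pair_flights):
        is_pair = int(f >= n_solo_flights)
        u = rng.normal(0.0, flight_sd_hz)
        spacing = (
            rng.uniform(0.0, max_spacing_m, size=beats_per_flight)
            if is_pair
            else np.zeros(beats_per_flight)
        )
        mean = base_hz + u + is_pair * (
            pair_intercept_hz + spacing_slope_hz_per_m * spacing
        )
        freq = mean + rng.normal(0.0, residual_sd_hz, size=beats_per_flight)
        rows.append(
            pd.DataFrame(
                {
                    "flight_id": f"W{f:04d}",
                    "is_pair": is_pair,
                    "spacing_m": spacing,
                    "freq_hz": freq,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
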