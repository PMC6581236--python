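"""Scenario assembly and dataset emission.

A scenario follows the four-phase design: each bird flies solo releases
(phase 1), similar-sized pair releases (phase 2), different-sized pair
releases (phase 3) and solo releases again (phase 4).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .. import io as pfio
from .config import (
    BirdRecord,
    FlightPlan,
    PopulationConfig,
    ScenarioConfig,
    TruthRecord,
)
from .birds import make_birds

__all__ = ["build_scenario", "emit_dataset"]

_EPOCH0 = 1.44e9  # arbitrary fixed origin for release timestamps


def _draw_weather(rng, cfg: ScenarioConfig) -> dict:
    return {
        "wind_speed_ms": float(rng.uniform(0.0, cfg.max_wind_ms)),
        "wind_dir_deg": float(rng.uniform(0.0, 360.0)),
        "temp_c": float(np.clip(rng.normal(18.0, 4.0), 2.0, 35.0)),
        "humidity_pct": float(rng.uniform(40.0, 90.0)),
        "pressure_hpa": float(rng.normal(1013.0, 8.0)),
    }


def build_scenario(
    scenario: ScenarioConfig | None = None,
    truth: TruthRecord | None = None,
    pop: PopulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[BirdRecord], list[FlightPlan]]:
    """Birds plus the full four-phase flight schedule with per-release weather.

    Similar-sized pairs are adjacent birds in tarsus order; different-sized
    pairs match the smallest half against the largest half.
    """
    scenario = scenario or ScenarioConfig()
    truth = truth or TruthRecord()
    rng = np.random.default_rng([seed, 7])
    birds = make_birds(scenario.n_birds, seed, pop)
    by_tarsus = sorted(birds, key=lambda b: b.tarsus_mm)
    n = len(birds)
    similar = [(by_tarsus[i], by_tarsus[i + 1]) for i in range(0, n, 2)]
    different = [(by_tarsus[i], by_tarsus[i + n // 2]) for i in range(n // 2)]

    plans: list[FlightPlan] = []
    epoch = _EPOCH0
    fid = 0
    for phase in (1, 2, 3, 4):
        for rep in range(scenario.flights_per_phase):
            if phase in (1, 4):
                for b in birds:
                    plans.append(
                        FlightPlan(
                            flight_id=f"F{fid:04d}",
                            phase=phase,
                            condition="solo",
                            bird_ids=(b.bird_id,),
                            release_epoch=epoch,
                            **_draw_weather(rng, scenario),
                        )
                    )
                    fid += 1
                    epoch += scenario.release_interval_s
            else:
                pairs = similar if phase == 2 else different
                for a, b in pairs:
                    plans.append(
                        FlightPlan(
                            flight_id=f"F{fid:04d}",
                            phase=phase,
                            condition="pair",
                            bird_ids=(a.bird_id, b.bird_id),
                            pair_id=f"{a.bird_id}-{b.bird_id}",
                            release_epoch=epoch,
                            **_draw_weather(rng, scenario),
                        )
                    )
                    fid += 1
                    epoch += scenario.release_interval_s
    return birds, plans


def emit_dataset(
    plans: list[FlightPlan],
    tracks: dict,
    traces: dict,
    birds: list[BirdRecord],
    truth: TruthRecord,
    out_dir: Path | str,
) -> dict[str, Path]:
    """Write birds/flights/gps/accel/weather CSVs plus truth.json.

    ``tracks`` and ``traces`` map flight_id -> {bird_id -> GpsTrack/AccelTrace}
    and may omit flights entirely, but any present entry must agree with the
    plan's bird ids; mismatches raise with the offending ids listed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry_ids = {b.bird_id for b in birds}
    offenders = []
    plan_ids = set()
    for p in plans:
        plan_ids.add(p.flight_id)
        for bid in p.bird_ids:
            if bid not in registry_ids:
                offenders.append(f"{p.flight_id}: unknown bird {bid}")
    for name, mapping in (("tracks", tracks), ("traces", traces)):
        for fid, per_bird in mapping.items():
            if fid not in plan_ids:
                offenders.append(f"{name}: unknown flight {fid}")
                continue
            plan = next(p for p in plans if p.flight_id == fid)
            extra = set(per_bird) - set(plan.bird_ids)
            if extra:
                offenders.append(f"{name}/{fid}: unexpected birds {sorted(extra)}")
    if offenders:
        raise ValueError("id mismatch: " + "; ".join(offenders))

    paths = {}
    paths["birds"] = out / "birds.csv"
    pfio.write_csv_atomic(pfio.birds_to_frame(birds), paths["birds"])
    paths["flights"] = out / "flights.csv"
    pfio.write_csv_atomic(pfio.plans_to_frame(plans), paths["flights"])

    gps_rows = []
    for p in plans:
        for bid, trk in tracks.get(p.flight_id, {}).items():
            gps_rows.append(
                pd.DataFrame(
                    {
                        "flight_id": p.flight_id,
                        "bird_id": bid,
                        "t_s": trk.t,
                        "lat_deg": trk.lat,
                        "lon_deg": trk.lon,
                    }
                )
            )
    gps = (
        pd.concat(gps_rows, ignore_index=True)
        if gps_rows
        else pd.DataFrame(columns=pfio.SCHEMAS["gps.csv"])
    )
    paths["gps"] = out / "gps.csv"
    pfio.write_csv_atomic(gps, paths["gps"])

    accel_rows = []
    for p in plans:
        for bid, tr in traces.get(p.flight_id, {}).items():
            accel_rows.append(
                pd.DataFrame(
                    {
                        "flight_id": p.flight_id,
                        "bird_id": bid,
                        "t_s": tr.t,
                        "ax_g": tr.ax,
                        "ay_g": tr.ay,
                        "az_g": tr.az,
                    }
                )
            )
    accel = (
        pd.concat(accel_rows, ignore_index=True)
        if accel_rows
        else pd.DataFrame(columns=pfio.SCHEMAS["accel.csv"])
    )
    paths["accel"] = out / "accel.csv"
    pfio.write_csv_atomic(accel, paths["accel"])

    weather = pd.DataFrame(
        [
            {
                "t_epoch": p.release_epoch,
                "wind_speed_ms": p.wind_speed_ms,
                "wind_dir_deg": p.wind_dir_deg,
                "temp_c": p.temp_c,
                "humidity_pct": p.humidity_pct,
                "pressure_hpa": p.pressure_hpa,
            }
            for p in plans
        ],
        columns=pfio.SCHEMAS["weather.csv"],
    )
    paths["weather"] = out / "weather.csv"
    pfio.write_csv_atomic(weather, paths["weather"])

    truth_doc = truth.to_dict()
    truth_doc["solo_freq_hz"] = {b.bird_id: b.solo_freq_hz for b in birds}
    paths["truth"] = out / "truth.json"
    pfio.write_json_atomic(truth_doc, paths["truth"])
    return paths
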