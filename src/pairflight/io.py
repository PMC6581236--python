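"""Plain-CSV readers and writers for the pipeline's fixed schemas.

All artifacts are header-first CSV; times are seconds-since-release floats,
angles degrees. Writers go through a temp file and an atomic rename.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import pandas as pd

from .kinematics import AccelTrace
from .synthio.config import BirdRecord, FlightPlan
from .trackgeo import GpsTrack

SCHEMAS = {
    "birds.csv": ["bird_id", "tarsus_mm", "mass_g"],
    "flights.csv": ["flight_id", "phase", "condition", "pair_id", "bird_ids", "release_epoch"],
    "gps.csv": ["flight_id", "bird_id", "t_s", "lat_deg", "lon_deg"],
    "accel.csv": ["flight_id", "bird_id", "t_s", "ax_g", "ay_g", "az_g"],
    "weather.csv": ["t_epoch", "wind_speed_ms", "wind_dir_deg", "temp_c", "humidity_pct", "pressure_hpa"],
}


def write_csv_atomic(df: pd.DataFrame, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def write_json_atomic(obj, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, sort_keys=True))
    os.replace(tmp, path)


def read_birds(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str}, float_precision="round_trip")
    _require(df, SCHEMAS["birds.csv"], path)
    return df


def read_flights(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"flight_id": str, "pair_id": str, "bird_ids": str},
        float_precision="round_trip",
    )
    _require(df, SCHEMAS["flights.csv"], path)
    return df


def read_gps(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"flight_id": str, "bird_id": str}, float_precision="round_trip")
    _require(df, SCHEMAS["gps.csv"], path)
    return df


def read_accel(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"flight_id": str, "bird_id": str}, float_precision="round_trip")
    _require(df, SCHEMAS["accel.csv"], path)
    return df


def read_weather(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, SCHEMAS["weather.csv"], path)
    return df


def read_truth(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def gps_frame_to_tracks(gps: pd.DataFrame) -> dict[tuple[str, str], GpsTrack]:
    """Split a gps.csv frame into GpsTrack objects keyed (flight_id, bird_id)."""
    out = {}
    for (fid, bid), grp in gps.groupby(["flight_id", "bird_id"], sort=True):
        grp = grp.sort_values("t_s")
        out[(fid, bid)] = GpsTrack(
            t=grp["t_s"].to_numpy(),
            lat=grp["lat_deg"].to_numpy(),
            lon=grp["lon_deg"].to_numpy(),
            flight_id=fid,
            bird_id=bid,
        )
    return out


def accel_frame_to_traces(
    accel: pd.DataFrame, sample_rate_hz: float = 200.0
) -> dict[tuple[str, str], AccelTrace]:
    """Split an accel.csv frame into AccelTrace objects keyed (flight_id, bird_id)."""
    out = {}
    for (fid, bid), grp in accel.groupby(["flight_id", "bird_id"], sort=True):
        grp = grp.sort_values("t_s")
        out[(fid, bid)] = AccelTrace(
            t=grp["t_s"].to_numpy(),
            ax=grp["ax_g"].to_numpy(),
            ay=grp["ay_g"].to_numpy(),
            az=grp["az_g"].to_numpy(),
            sample_rate_hz=sample_rate_hz,
        )
    return out


def birds_to_frame(birds: list[BirdRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"bird_id": b.bird_id, "tarsus_mm": b.tarsus_mm, "mass_g": b.mass_g}
            for b in birds
        ]
    )


def plans_to_frame(plans: list[FlightPlan]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "flight_id": p.flight_id,
                "phase": p.phase,
                "condition": p.condition,
                "pair_id": p.pair_id or "",
                "bird_ids": ";".join(p.bird_ids),
                "release_epoch": p.release_epoch,
            }
            for p in plans
        ]
    )


def frame_to_plans(flights: pd.DataFrame, weather: pd.DataFrame) -> list[FlightPlan]:
    """Rebuild FlightPlan objects, joining per-release weather by epoch."""
    wx = weather.set_index("t_epoch")
    plans = []
    for row in flights.itertuples(index=False):
        w = wx.loc[row.release_epoch]
        pair_id = row.pair_id if isinstance(row.pair_id, str) and row.pair_id else None
        plans.append(
            FlightPlan(
                flight_id=row.flight_id,
                phase=int(row.phase),
                condition=row.condition,
                bird_ids=tuple(row.bird_ids.split(";")),
                pair_id=pair_id,
                release_epoch=float(row.release_epoch),
                wind_speed_ms=float(w["wind_speed_ms"]),
                wind_dir_deg=float(w["wind_dir_deg"]),
                temp_c=float(w["temp_c"]),
                humidity_pct=float(w["humidity_pct"]),
                pressure_hpa=float(w["pressure_hpa"]),
            )
        )
    return plans
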