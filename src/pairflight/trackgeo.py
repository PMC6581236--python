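"""GPS trajectory geometry.

Great-circle distances and bearings on a spherical Earth, track trimming
around release/home sites, route-accuracy (distance-weighted mean cosine of
the heading-to-goal angle), and paired-flight spacing/leadership analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "GpsTrack",
    "PairContext",
    "haversine_m",
    "forward_azimuth",
    "destination_point",
    "route_accuracy",
    "trim_radius",
    "pair_spacing_and_masks",
]


@dataclass
class GpsTrack:
    """A time-ordered sequence of GPS fixes for one bird on one flight."""

    t: np.ndarray  # seconds since release
    lat: np.ndarray  # degrees WGS-84
    lon: np.ndarray  # degrees WGS-84
    flight_id: str = ""
    bird_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (len(self.t) == len(self.lat) == len(self.lon)):
            raise ValueError("t, lat, lon must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError("latitude out of [-90, 90]")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def step_dist_m(self) -> np.ndarray:
        """Orthodromic distance of each step (length n-1)."""
        return haversine_m(
            (self.lat[:-1], self.lon[:-1]), (self.lat[1:], self.lon[1:])
        )

    @property
    def heading_deg(self) -> np.ndarray:
        """Forward azimuth of each step (length n-1), degrees [0, 360)."""
        return forward_azimuth(
            (self.lat[:-1], self.lon[:-1]), (self.lat[1:], self.lon[1:])
        )

    @property
    def ground_speed_ms(self) -> np.ndarray:
        """Per-step ground speed (length n-1)."""
        return self.step_dist_m / np.diff(self.t)

    def path_length_m(self) -> float:
        return float(np.sum(self.step_dist_m))


@dataclass
class PairContext:
    """Spacing and leadership summary for one paired flight."""

    pair_id: str
    spacing_m: np.ndarray  # per matched fix
    t_matched: np.ndarray
    front_bird_id: str
    front_fraction: float  # share of matched fixes led by front_bird_id
    consistent_leader: bool  # front_fraction > leader threshold
    include_mask: np.ndarray = field(default=None)  # spacing<50m AND majority leader in front

    def __post_init__(self) -> None:
        if np.any(self.spacing_m < 0):
            raise ValueError("spacing must be non-negative")
        if not 0.0 <= self.front_fraction <= 1.0:
            raise ValueError("front_fraction must lie in [0, 1]")


def _check_latlon(lat: np.ndarray) -> None:
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of [-90, 90]")


def haversine_m(p1, p2, radius_m: float = EARTH_RADIUS_M):
    """Great-circle distance in metres between (lat, lon) points (degrees).

    Accepts scalars or arrays; broadcasts elementwise.
    """
    lat1, lon1 = (np.asarray(x, dtype=float) for x in p1)
    lat2, lon2 = (np.asarray(x, dtype=float) for x in p2)
    _check_latlon(lat1)
    _check_latlon(lat2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * radius_m * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def forward_azimuth(p1, p2):
    """Initial great-circle bearing from p1 to p2, degrees in [0, 360).

    0 = north, clockwise positive. Raises for coincident points (scalar input).
    """
    lat1, lon1 = (np.asarray(x, dtype=float) for x in p1)
    lat2, lon2 = (np.asarray(x, dtype=float) for x in p2)
    _check_latlon(lat1)
    _check_latlon(lat2)
    if lat1.ndim == 0 and np.allclose([lat1, lon1], [lat2, lon2]):
        raise ValueError("forward azimuth undefined for coincident points")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlmb = np.radians(lon2 - lon1)
    y = np.sin(dlmb) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlmb)
    brg = np.degrees(np.arctan2(y, x)) % 360.0
    return brg if brg.ndim else float(brg)


def destination_point(lat, lon, bearing_deg, dist_m, radius_m: float = EARTH_RADIUS_M):
    """Point reached from (lat, lon) travelling dist_m on an initial bearing."""
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lmb1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(dist_m, dtype=float) / radius_m
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lmb2 = lmb1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lat2 = np.degrees(phi2)
    lon2 = (np.degrees(lmb2) + 540.0) % 360.0 - 180.0
    if np.ndim(lat2) == 0:
        return float(lat2), float(lon2)
    return lat2, lon2


def route_accuracy(track: GpsTrack, goal: tuple[float, float]) -> float:
    """Distance-weighted mean cosine of the angle between each step's heading
    and the bearing to the goal, in [-1, 1].

    1 means every step heads exactly at the goal; -1 means heading directly
    away. The bearing to the goal is recomputed at every fix, so the measure
    is well defined on arbitrary sub-tracks.
    """
    if len(track) < 2:
        raise ValueError("route_accuracy needs at least 2 fixes")
    d = track.step_dist_m
    moved = d > 0
    if not np.any(moved):
        raise ValueError("zero-length track: no displacement between fixes")
    heading = forward_azimuth(
        (track.lat[:-1][moved], track.lon[:-1][moved]),
        (track.lat[1:][moved], track.lon[1:][moved]),
    )
    goal_brg = forward_azimuth(
        (track.lat[:-1][moved], track.lon[:-1][moved]),
        (np.full(moved.sum(), goal[0]), np.full(moved.sum(), goal[1])),
    )
    theta = np.radians(heading - goal_brg)  # cosine is even & periodic
    dm = d[moved]
    return float(np.sum(dm * np.cos(theta)) / np.sum(dm))


def trim_radius(track: GpsTrack, sites, radius_m: float = 200.0) -> GpsTrack:
    """Drop fixes lying within radius_m of any site; order preserved."""
    if radius_m < 0:
        raise ValueError("radius must be non-negative")
    keep = np.ones(len(track), dtype=bool)
    for site in sites:
        d = haversine_m(
            (track.lat, track.lon),
            (np.full(len(track), site[0]), np.full(len(track), site[1])),
        )
        keep &= np.asarray(d) >= radius_m
    if not np.any(keep):
        warnings.warn("all fixes trimmed; returning empty track", stacklevel=2)
    return GpsTrack(
        t=track.t[keep],
        lat=track.lat[keep],
        lon=track.lon[keep],
        flight_id=track.flight_id,
        bird_id=track.bird_id,
    )


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(angles_deg)
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


def pair_spacing_and_masks(
    track_a: GpsTrack,
    track_b: GpsTrack,
    *,
    pair_id: str = "",
    spacing_threshold_m: float = 50.0,
    match_tolerance_s: float = 0.2,
    leader_fraction: float = 0.9,
) -> PairContext:
    """Match fixes of two tracks by nearest timestamp and summarise spacing
    and leadership.

    The inclusion mask is true where horizontal spacing < spacing_threshold_m
    and, when leadership swaps occur, where the majority-leader bird is in
    front. A flight whose front bird holds more than leader_fraction of
    matched fixes is flagged as having a consistent leader.
    """
    if len(track_a) < 1 or len(track_b) < 1:
        raise ValueError("both tracks must be non-empty")
    idx = np.searchsorted(track_b.t, track_a.t)
    idx = np.clip(idx, 1, len(track_b.t) - 1)
    prev_closer = np.abs(track_a.t - track_b.t[idx - 1]) < np.abs(
        track_a.t - track_b.t[idx]
    )
    idx = idx - prev_closer.astype(int)
    matched = np.abs(track_a.t - track_b.t[idx]) <= match_tolerance_s
    if not np.any(matched):
        raise ValueError("no fixes matched within time tolerance")
    ia = np.flatnonzero(matched)
    ib = idx[matched]

    lat_a, lon_a = track_a.lat[ia], track_a.lon[ia]
    lat_b, lon_b = track_b.lat[ib], track_b.lon[ib]
    spacing = np.atleast_1d(haversine_m((lat_a, lon_a), (lat_b, lon_b)))

    # Mean pair heading from both tracks' step headings (circular mean).
    headings = np.concatenate([track_a.heading_deg, track_b.heading_deg])
    mean_hdg = np.radians(_circular_mean_deg(headings))
    hdg_en = np.array([np.sin(mean_hdg), np.cos(mean_hdg)])  # east, north

    # Local-tangent vector from B to A, projected on mean heading.
    lat0 = np.radians(np.mean(np.concatenate([lat_a, lat_b])))
    east = np.radians(lon_a - lon_b) * np.cos(lat0) * EARTH_RADIUS_M
    north = np.radians(lat_a - lat_b) * EARTH_RADIUS_M
    proj = east * hdg_en[0] + north * hdg_en[1]  # >0: A in front
    a_front = proj > 0

    frac_a = float(np.mean(a_front))
    if frac_a >= 0.5:
        front_bird, front_frac, front_mask = track_a.bird_id, frac_a, a_front
    else:
        front_bird, front_frac, front_mask = track_b.bird_id, 1.0 - frac_a, ~a_front

    close = spacing < spacing_threshold_m
    include = close & front_mask
    return PairContext(
        pair_id=pair_id,
        spacing_m=spacing,
        t_matched=track_a.t[ia],
        front_bird_id=front_bird,
        front_fraction=front_frac,
        consistent_leader=front_frac > leader_fraction,
        include_mask=include,
    )
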