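"""Per-wingbeat kinematics from tri-axial accelerometer traces.

The dorsal (Z) channel oscillates once per wingbeat. After smoothing and
gravity removal, wingbeats are delimited by successive dynamic-acceleration
maxima; the downstroke phase runs from each maximum to the following
minimum and the upstroke from that minimum to the next maximum. Peak-to-peak
displacement comes from double trapezoidal integration with per-beat drift
control. Extremum times are refined to sub-sample precision by local
quadratic interpolation, so phase durations are not quantised to the sample
grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid

G_TO_MS2 = 9.80665

WINGBEAT_COLUMNS = [
    "start_s",
    "end_s",
    "freq_hz",
    "pp_accel_g",
    "pp_disp_mm",
    "down_ms",
    "up_ms",
]

__all__ = [
    "G_TO_MS2",
    "WINGBEAT_COLUMNS",
    "AccelTrace",
    "smooth",
    "remove_gravity",
    "butter_highpass",
    "detect_wingbeats",
    "stroke_phases",
    "pp_displacement",
    "dorsal_pipeline",
    "head_pipeline",
]


@dataclass
class AccelTrace:
    """Regularly sampled tri-axial acceleration in units of g."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float
    mount: str = "dorsal"  # dorsal | head

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for ch in ("ax", "ay", "az"):
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=float))
        n = len(self.t)
        if not all(len(getattr(self, ch)) == n for ch in ("ax", "ay", "az")):
            raise ValueError("all channels must match the length of t")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not (
            np.all(np.isfinite(self.ax))
            and np.all(np.isfinite(self.ay))
            and np.all(np.isfinite(self.az))
        ):
            raise ValueError("acceleration values must be finite")

    def __len__(self) -> int:
        return len(self.t)


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def smooth(trace: AccelTrace, window: int) -> AccelTrace:
    """Centered moving average over an odd number of samples per channel."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd sample count")
    if window == 1:
        return replace(trace)
    return replace(
        trace,
        ax=_running_mean(trace.ax, window),
        ay=_running_mean(trace.ay, window),
        az=_running_mean(trace.az, window),
    )


def remove_gravity(trace: AccelTrace, window_s: float = 2.75) -> AccelTrace:
    """Subtract a centered running mean spanning window_s seconds per channel.

    The window should cover many wingbeat cycles (default 2.75 s, roughly 15
    cycles at typical pigeon wingbeat frequencies) so the oscillatory
    component passes nearly unattenuated while gravity and slow drift are
    removed.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = int(round(window_s * trace.sample_rate_hz))
    if n > len(trace):
        raise ValueError("gravity window longer than trace")
    n = max(n, 1)
    return replace(
        trace,
        ax=trace.ax - _running_mean(trace.ax, n),
        ay=trace.ay - _running_mean(trace.ay, n),
        az=trace.az - _running_mean(trace.az, n),
    )


def butter_highpass(
    trace: AccelTrace, order: int = 4, cutoff_hz: float = 1.0
) -> AccelTrace:
    """Zero-phase (forward-backward) Butterworth high-pass per channel."""
    nyq = trace.sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie strictly below the Nyquist frequency")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=trace.sample_rate_hz, output="sos")
    return replace(
        trace,
        ax=signal.sosfiltfilt(sos, trace.ax),
        ay=signal.sosfiltfilt(sos, trace.ay),
        az=signal.sosfiltfilt(sos, trace.az),
    )


def _refine_extremum(
    y: np.ndarray, i: int, t0: float, dt: float, sign: float, half: int = 4
):
    """Sub-sample extremum time/value near sample i.

    Fits a piecewise quartic-in-offset with a shared vertex (even-order
    coefficients free on each side) over +-half samples, grid-searching the
    vertex location in three refinement stages. Unequal side curvatures
    occur whenever the two stroke phases have unequal durations, and a
    plain 3-point parabola is biased toward the flatter side there; the
    shared-vertex fit is not. ``sign`` is +1 for maxima, -1 for minima.
    """
    if i < half or i >= len(y) - half:
        return t0 + i * dt, y[i]
    idx = np.arange(i - half, i + half + 1)
    tt = idx * dt
    yy = sign * y[idx]
    ones = np.ones_like(tt)

    def sse_and_fit(tau: float):
        d = tt - tau
        d2 = d * d
        left = d < 0
        a = np.column_stack(
            [
                ones,
                np.where(left, d2, 0.0),
                np.where(left, 0.0, d2),
                np.where(left, d2 * d2, 0.0),
                np.where(left, 0.0, d2 * d2),
            ]
        )
        coef, *_ = np.linalg.lstsq(a, yy, rcond=None)
        r = yy - a @ coef
        return float(r @ r), coef

    center = i * dt
    best_tau, best_sse, best_coef = center, np.inf, None
    for span, npts in ((1.2 * dt, 13), (0.25 * dt, 11), (0.05 * dt, 11)):
        for tau in np.linspace(best_tau - span, best_tau + span, npts):
            sse, coef = sse_and_fit(tau)
            if sse < best_sse:
                best_sse, best_tau, best_coef = sse, tau, coef
    return t0 + best_tau, sign * best_coef[0]


def detect_wingbeats(
    trace: AccelTrace,
    *,
    min_separation_s: float = 0.055,
    prominence_frac: float = 0.3,
) -> pd.DataFrame:
    """Delimit wingbeats by successive maxima of the dynamic dorsal channel.

    Maxima are found by local-extremum search with a minimum peak separation
    (default 55 ms) and a minimum prominence expressed as a fraction of the
    channel's inter-quartile range. Input must already be gravity-removed.
    Returns a frame with start_s, end_s, freq_hz and pp_accel_g; fewer than 3
    peaks yields an empty frame with a warning.
    """
    z = trace.az
    dt = 1.0 / trace.sample_rate_hz
    distance = max(1, int(round(min_separation_s * trace.sample_rate_hz)))
    q75, q25 = np.percentile(z, [75, 25])
    prominence = prominence_frac * (q75 - q25)
    peaks, _ = signal.find_peaks(z, distance=distance, prominence=max(prominence, 0.0) or None)
    if len(peaks) < 3:
        warnings.warn("fewer than 3 acceleration maxima detected; empty table", stacklevel=2)
        return pd.DataFrame(columns=["start_s", "end_s", "freq_hz", "pp_accel_g", "peak_idx_start", "peak_idx_end"])

    t0 = trace.t[0]
    refined = [_refine_extremum(z, int(i), t0, dt, +1.0) for i in peaks]
    tpk = np.array([r[0] for r in refined])

    rows = []
    for k in range(len(peaks) - 1):
        i0, i1 = int(peaks[k]), int(peaks[k + 1])
        period = tpk[k + 1] - tpk[k]
        seg = z[i0 : i1 + 1]
        jmin = i0 + int(np.argmin(seg))
        _, vmin = _refine_extremum(z, jmin, t0, dt, -1.0)
        vmax = max(refined[k][1], refined[k + 1][1])
        rows.append(
            {
                "start_s": tpk[k],
                "end_s": tpk[k + 1],
                "freq_hz": 1.0 / period,
                "pp_accel_g": vmax - vmin,
                "peak_idx_start": i0,
                "peak_idx_end": i1,
            }
        )
    return pd.DataFrame(rows)


def stroke_phases(trace: AccelTrace, wingbeats: pd.DataFrame) -> pd.DataFrame:
    """Add down_ms (max -> min) and up_ms (min -> max) to a wingbeat table.

    The minimum within each beat anchors the phase boundary; the two phase
    durations sum to the beat period exactly. Ties between equal minima take
    the earliest sample and emit a warning.
    """
    if wingbeats.empty:
        out = wingbeats.copy()
        out["down_ms"] = pd.Series(dtype=float)
        out["up_ms"] = pd.Series(dtype=float)
        return out
    z = trace.az
    dt = 1.0 / trace.sample_rate_hz
    t0 = trace.t[0]
    down = np.empty(len(wingbeats))
    up = np.empty(len(wingbeats))
    tied = 0
    for r, row in enumerate(wingbeats.itertuples(index=False)):
        i0, i1 = int(row.peak_idx_start), int(row.peak_idx_end)
        seg = z[i0 : i1 + 1]
        jrel = int(np.argmin(seg))
        if np.count_nonzero(seg == seg[jrel]) > 1:
            tied += 1
        tmin, _ = _refine_extremum(z, i0 + jrel, t0, dt, -1.0)
        down[r] = (tmin - row.start_s) * 1000.0
        up[r] = (row.end_s - tmin) * 1000.0
    if tied:
        warnings.warn(f"{tied} beats had tied minima; earliest sample taken", stacklevel=2)
    out = wingbeats.copy()
    out["down_ms"] = down
    out["up_ms"] = up
    return out


def pp_displacement(trace: AccelTrace, wingbeats: pd.DataFrame) -> pd.DataFrame:
    """Add per-beat peak-to-peak displacement (mm) by double integration.

    The dynamic channel is converted to m s-2, integrated twice with the
    trapezoidal rule; within each beat the velocity is de-meaned and the
    displacement linearly detrended before taking max - min. Beats shorter
    than 3 samples get NaN.
    """
    out = wingbeats.copy()
    if wingbeats.empty:
        out["pp_disp_mm"] = pd.Series(dtype=float)
        return out
    a = trace.az * G_TO_MS2
    dt = 1.0 / trace.sample_rate_hz
    disp = np.full(len(wingbeats), np.nan)
    for r, row in enumerate(wingbeats.itertuples(index=False)):
        i0, i1 = int(row.peak_idx_start), int(row.peak_idx_end)
        if i1 - i0 + 1 < 3:
            continue
        seg = a[i0 : i1 + 1]
        v = cumulative_trapezoid(seg, dx=dt, initial=0.0)
        v -= v.mean()
        x = cumulative_trapezoid(v, dx=dt, initial=0.0)
        x = signal.detrend(x, type="linear")
        disp[r] = (x.max() - x.min()) * 1000.0
    out["pp_disp_mm"] = disp
    return out


def dorsal_pipeline(
    trace: AccelTrace,
    *,
    smooth_window: int = 3,
    gravity_window_s: float = 2.75,
    min_separation_s: float = 0.055,
    prominence_frac: float = 0.3,
) -> pd.DataFrame:
    """Full dorsal processing chain: smooth, remove gravity, segment
    wingbeats, measure stroke phases and displacement."""
    dyn = remove_gravity(smooth(trace, smooth_window), gravity_window_s)
    wb = detect_wingbeats(
        dyn, min_separation_s=min_separation_s, prominence_frac=prominence_frac
    )
    wb = stroke_phases(dyn, wb)
    wb = pp_displacement(dyn, wb)
    return wb


def head_pipeline(
    trace: AccelTrace,
    *,
    smooth_window: Optional[int] = 5,
    order: int = 4,
    cutoff_hz: float = 1.0,
    min_separation_s: float = 0.055,
    prominence_frac: float = 0.3,
) -> pd.DataFrame:
    """Head-mounted variant: smooth, zero-phase high-pass, then segment and
    integrate the vertical channel.

    Pass smooth_window=None to skip smoothing (the moving average is not
    amplitude-neutral at wingbeat frequencies for short windows at low
    sample rates).
    """
    dyn = trace if smooth_window is None else smooth(trace, smooth_window)
    dyn = butter_highpass(dyn, order=order, cutoff_hz=cutoff_hz)
    wb = detect_wingbeats(
        dyn, min_separation_s=min_separation_s, prominence_frac=prominence_frac
    )
    wb = stroke_phases(dyn, wb)
    wb = pp_displacement(dyn, wb)
    return wb
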