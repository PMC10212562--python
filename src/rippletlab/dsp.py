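"""Shared signal-processing helpers: zero-phase low-pass and sub-sample peaks."""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["lowpass", "parabolic_peak_time", "refine_extremum"]


def lowpass(x: np.ndarray, rate_hz: float, cutoff_hz: float = 1300.0,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (mirrors the acquisition filter)."""
    nyq = rate_hz / 2.0
    if cutoff_hz >= nyq:
        return np.asarray(x, float)
    sos = signal.butter(order, cutoff_hz / nyq, output="sos")
    return signal.sosfiltfilt(sos, x)


def parabolic_peak_time(y: np.ndarray, idx: int, dt_ms: float) -> tuple[float, float]:
    """Sub-sample peak location by 3-point parabolic interpolation.

    Returns (time_ms, value) of the vertex of the parabola through
    ``y[idx-1:idx+2]``; falls back to the sample itself at array edges or
    when the three points are collinear.
    """
    if idx <= 0 or idx >= len(y) - 1:
        return idx * dt_ms, float(y[idx])
    y0, y1, y2 = float(y[idx - 1]), float(y[idx]), float(y[idx + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return idx * dt_ms, y1
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    value = y1 - 0.25 * (y0 - y2) * delta
    return (idx + delta) * dt_ms, value


def refine_extremum(y: np.ndarray, idx: int, dt_ms: float,
                    mode: str = "min") -> tuple[float, float]:
    """Parabolic refinement of a local minimum or maximum at sample ``idx``."""
    if mode == "min":
        t, v = parabolic_peak_time(-np.asarray(y, float), idx, dt_ms)
        return t, -v
    return parabolic_peak_time(np.asarray(y, float), idx, dt_ms)
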