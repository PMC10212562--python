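"""Averaged-LFP decomposition and ripplet feature extraction.

A ripplet is a transient (<25 ms) LFP oscillation of 2-5 negative transients
at roughly 400 Hz riding on a slow positive envelope, preceded by the
presynaptic thalamocortical volley. Pharmacology separates the components:
TTX leaves only the stimulus artifact (subtracted from everything),
CNQX+APV leaves artifact + presynaptic volleys, and the control-minus-blocked
difference is the purely postsynaptic ripplet.

Feature times are reported in ms from light onset, localized to sub-sample
precision by parabolic interpolation after zero-phase low-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .core import StimulusProtocol, Trace, ValidationError, get_logger
from .dsp import lowpass, refine_extremum

__all__ = [
    "LfpConfig",
    "RippletFeatures",
    "subtract_artifact",
    "isolate_postsynaptic",
    "detect_ripplet_features",
    "oscillation_frequency",
    "gaussian_components",
]

log = get_logger(__name__)


@dataclass(frozen=True)
class LfpConfig:
    """Tunables of the ripplet detector (times in ms, amplitudes in mV)."""

    amplitude_threshold_mv: float = 0.1      # transient candidacy
    inclusion_threshold_mv: float = 0.5      # slice-level analyzable criterion
    min_period_ms: float = 1.5               # below smallest inter-peak interval
    volley_window_ms: tuple[float, float] = (1.0, 3.5)   # post onset
    transient_window_ms: tuple[float, float] = (3.0, 20.0)
    lowpass_hz: float = 1300.0


@dataclass
class RippletFeatures:
    """Feature set of one averaged LFP (all times ms from light onset)."""

    presyn_volley_times: np.ndarray
    transient_times: np.ndarray          # negative maxima (ripplet peaks)
    trough_times: np.ndarray             # positive maxima, leading trough first
    transient_amplitudes: np.ndarray     # mV, positive magnitudes
    frequency: float | None              # Hz, defined for >= 2 transients
    below_amplitude_criterion: bool = False

    @property
    def n_transients(self) -> int:
        return len(self.transient_times)

    def to_dict(self) -> dict:
        return {
            "presyn_volley_times_ms": list(map(float, self.presyn_volley_times)),
            "transient_times_ms": list(map(float, self.transient_times)),
            "trough_times_ms": list(map(float, self.trough_times)),
            "transient_amplitudes_mv": list(map(float, self.transient_amplitudes)),
            "frequency_hz": None if self.frequency is None else float(self.frequency),
            "n_transients": self.n_transients,
            "below_amplitude_criterion": self.below_amplitude_criterion,
        }


def _check_same_shape(a: Trace, b: Trace) -> None:
    if len(a) != len(b) or a.rate != b.rate:
        raise ValidationError("traces must share rate and length")


def subtract_artifact(control_avg: Trace, ttx_avg: Trace) -> Trace:
    """Remove the (opto)electrical square artifact: pointwise control - TTX."""
    _check_same_shape(control_avg, ttx_avg)
    return Trace(control_avg.samples - ttx_avg.samples,
                 rate=control_avg.rate, kind=control_avg.kind,
                 holding=control_avg.holding)


def isolate_postsynaptic(control_avg: Trace, blocked_avg: Trace) -> Trace:
    """Isolate the postsynaptic ripplet: control minus the CNQX+APV trace."""
    _check_same_shape(control_avg, blocked_avg)
    return Trace(control_avg.samples - blocked_avg.samples,
                 rate=control_avg.rate, kind=control_avg.kind,
                 holding=control_avg.holding)


def _window_indices(t_ms: np.ndarray, onset: float, window: tuple[float, float]):
    return np.flatnonzero((t_ms >= onset + window[0]) & (t_ms <= onset + window[1]))


def _detect_minima(y: np.ndarray, idxs: np.ndarray, dt_ms: float,
                   depth: float, min_period_ms: float):
    """Deepest-first local minima below ``-depth`` with enforced separation."""
    if idxs.size < 3:
        return []
    seg = y[idxs]
    peaks, _ = _signal.find_peaks(-seg, height=depth)
    cands = sorted(((seg[i], idxs[i]) for i in peaks))
    kept: list[tuple[float, float]] = []
    for val, gi in cands:
        t, v = refine_extremum(y, gi, dt_ms, mode="min")
        if all(abs(t - tk) >= min_period_ms for tk, _ in kept):
            kept.append((t, v))
    kept.sort()
    return kept


def detect_ripplet_features(
    avg: Trace,
    protocol: StimulusProtocol,
    config: LfpConfig | None = None,
    blocked_avg: Trace | None = None,
) -> RippletFeatures:
    """Extract volley/transient/trough times from an averaged LFP.

    Transients are local minima below the amplitude threshold within the
    post-onset transient window, separated by at least ``min_period_ms``;
    troughs are the positive maxima between consecutive transients plus the
    trough preceding the first transient. Presynaptic volleys are measured
    on ``blocked_avg`` (the CNQX+APV average) when given, else on the early
    segment of ``avg``. A slice whose largest transient is below the 0.5 mV
    inclusion criterion is returned flagged, with empty features.
    """
    if avg.kind != "lfp":
        raise ValidationError("ripplet detection expects an LFP trace")
    config = config or LfpConfig()
    dt = avg.dt_ms
    t_ms = avg.times_ms
    y = lowpass(avg.samples, avg.rate, config.lowpass_hz)
    onset = protocol.onset

    tw = _window_indices(t_ms, onset, config.transient_window_ms)
    transients = _detect_minima(y, tw, dt, config.amplitude_threshold_mv,
                                config.min_period_ms)
    if not transients or max(-v for _, v in transients) < config.inclusion_threshold_mv:
        log.info("ripplet below amplitude criterion (max %.3f mV)",
                 max((-v for _, v in transients), default=0.0))
        empty = np.array([])
        return RippletFeatures(empty, empty, empty, empty, None,
                               below_amplitude_criterion=True)

    trans_t = np.array([tt for tt, _ in transients])
    trans_a = np.array([-v for _, v in transients])

    # troughs: maxima between consecutive transients, plus the leading trough
    troughs = []
    period = float(np.median(np.diff(trans_t))) if len(trans_t) > 1 else 2.5
    lead_lo = max(onset, trans_t[0] - period)
    pairs = [(lead_lo, trans_t[0])] + list(zip(trans_t[:-1], trans_t[1:]))
    for lo, hi in pairs:
        seg = np.flatnonzero((t_ms > lo) & (t_ms < hi))
        if seg.size < 3:
            continue
        gi = seg[np.argmax(y[seg])]
        tt, _ = refine_extremum(y, gi, dt, mode="max")
        troughs.append(tt)
    troughs = np.asarray(troughs)

    # presynaptic volleys: prefer the blocked (CNQX+APV) trace when supplied
    vsrc = lowpass(blocked_avg.samples, blocked_avg.rate, config.lowpass_hz) \
        if blocked_avg is not None else y
    vt_ms = blocked_avg.times_ms if blocked_avg is not None else t_ms
    vw = _window_indices(vt_ms, onset, config.volley_window_ms)
    volleys = _detect_minima(vsrc, vw, dt, config.amplitude_threshold_mv / 2.0,
                             config.min_period_ms)
    volley_t = np.array([tt for tt, _ in volleys])

    freq = oscillation_frequency(trans_t) if len(trans_t) >= 2 else None
    return RippletFeatures(
        presyn_volley_times=volley_t - onset,
        transient_times=trans_t - onset,
        trough_times=troughs - onset,
        transient_amplitudes=trans_a,
        frequency=freq,
    )


def oscillation_frequency(times) -> float:
    """Average frequency = 1 / average inter-event interval, in Hz.

    For n strictly increasing event times this is ``(n-1)/(t_n - t_1)``
    (times in ms), i.e. the reciprocal of the mean ISI.
    """
    times = np.asarray(times, float)
    if times.size < 2:
        raise ValidationError("need >= 2 event times for a frequency")
    if not np.all(np.diff(times) > 0):
        raise ValidationError("event times must be strictly increasing")
    return (times.size - 1) / (times[-1] - times[0]) * 1000.0


def gaussian_components(times_by_order: dict, bin_width: float):
    """Model each event order's time histogram as a Gaussian.

    Each order's component has the same mean, SD (n-1 denominator) and
    integral (count x bin width) as its histogram. Orders with fewer than
    two times are omitted with a warning; zero-SD components are flagged
    degenerate.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    out = {}
    for order, times in times_by_order.items():
        times = np.asarray(times, float)
        if times.size < 2:
            log.warning("order %s has <2 times; omitted from Gaussian model", order)
            continue
        sd = float(np.std(times, ddof=1))
        if sd == 0.0:
            log.warning("order %s has zero SD; degenerate Gaussian", order)
        out[order] = {
            "mean": float(np.mean(times)),
            "sd": sd,
            "area": float(times.size * bin_width),
            "degenerate": sd == 0.0,
        }
    return out
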