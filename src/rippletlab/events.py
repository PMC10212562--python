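"""EPSC/IPSC onset detection in voltage-clamp sweeps and charge analysis.

At a holding potential between -55 and -50 mV, EPSCs appear as negative and
IPSCs as positive deflections, so a single trace reveals the alternating
excitation-inhibition sequence of a ripplet cycle. Onsets (marked by eye in
experimental practice) are operationalized as slope steps: a synaptic
current's derivative jumps at its onset, which a matched forward-minus-
backward step detector picks out even when events ride each other's decays.
The merged onset order is forced to alternate by dropping the smaller of two
consecutive same-sign events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi, signal as _signal, stats as _stats

from .core import StimulusProtocol, Trace, ValidationError, get_logger
from .dsp import refine_extremum

__all__ = [
    "EIConfig",
    "EISequence",
    "detect_ei_onsets",
    "net_charge",
    "trough_epsc_regression",
]

log = get_logger(__name__)

# a candidate event's onset slope step must reach this fraction of the
# strongest step in the response, or the "event" is just a return toward
# baseline between two genuine events
_ONSET_STEP_FRAC = 0.08


@dataclass(frozen=True)
class EIConfig:
    mad_threshold: float = 5.0          # event amplitude, in baseline MADs
    min_separation_ms: float = 0.8
    baseline_ms: float = 10.0           # pre-onset window used as baseline
    smooth_sigma_ms: float = 0.075      # Gaussian pre-smoothing (no ringing)
    step_window_ms: float = 0.15        # slope-step matched-detector half-width
    # skip past the previous event's onset AND its post-onset slope recovery
    # (a sharp PSC rebounds its slope within ~2 rise times of the onset)
    onset_guard_ms: float = 0.5


@dataclass
class EISequence:
    """Alternating EPSC/IPSC onsets (ms) and peak amplitudes (pA)."""

    epsc_onsets: np.ndarray
    ipsc_onsets: np.ndarray
    epsc_amplitudes: np.ndarray
    ipsc_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        merged = self.merged()
        if merged and not all(
                a[1] != b[1] for a, b in zip(merged[:-1], merged[1:])):
            raise ValidationError("E-I sequence must strictly alternate")

    def merged(self) -> list[tuple[float, str]]:
        ev = [(float(t), "E") for t in self.epsc_onsets] + \
             [(float(t), "I") for t in self.ipsc_onsets]
        return sorted(ev)

    def to_dict(self) -> dict:
        return {
            "epsc_onsets_ms": list(map(float, self.epsc_onsets)),
            "ipsc_onsets_ms": list(map(float, self.ipsc_onsets)),
            "epsc_amplitudes_pa": list(map(float, self.epsc_amplitudes)),
            "ipsc_amplitudes_pa": list(map(float, self.ipsc_amplitudes)),
        }


def _baseline(t: Trace, protocol: StimulusProtocol, config: EIConfig):
    times = t.times_ms
    m = (times >= protocol.onset - config.baseline_ms) & (times < protocol.onset)
    if not np.any(m):
        m = times < protocol.onset
    return t.samples[m]


def detect_ei_onsets(t: Trace, protocol: StimulusProtocol,
                     config: EIConfig | None = None) -> EISequence:
    """Detect the alternating EPSC/IPSC onset sequence in one VC trace.

    Because successive EPSCs and IPSCs overlap (the cycle is shorter than
    the PSC decay), events are found in two stages. Event extrema are local
    deflections whose *prominence* exceeds ``mad_threshold`` baseline MADs
    (events ride each other's decays, so absolute height is meaningless);
    the deflection sign gives the class. Each event's onset is then located
    with a matched step detector on the first derivative: a PSC kernel's
    slope jumps at its onset, so the forward-minus-backward short-window
    slope difference spikes there while suppressing the smooth slope changes
    of neighbouring peaks and decays. Candidates whose step is weak or sits
    at the search-window edge are returns toward baseline, not events, and
    are dropped. Alternation is enforced by dropping the smaller of two
    consecutive same-sign events (logged) -- the first IPSC of a sweep is
    often occluded by an unclamped spike, so a leading lone EPSC is
    legitimate.
    """
    if t.kind != "voltage_clamp":
        raise ValidationError("E-I detection expects a voltage-clamp trace")
    if t.holding is None or not (-55.0 <= t.holding <= -50.0):
        raise ValidationError("holding must lie in [-55, -50] mV")
    config = config or EIConfig()
    dt = t.dt_ms
    base = _baseline(t, protocol, config)
    sigma = max(1.0, config.smooth_sigma_ms / dt)
    y = _ndi.gaussian_filter1d(t.samples.astype(float), sigma) - np.median(base)
    mad = float(_stats.median_abs_deviation(base, scale="normal"))
    height = config.mad_threshold * max(mad, 1e-9)
    dist = max(1, int(round(config.min_separation_ms / dt)))
    start = int(round(protocol.onset / dt))

    # stage 1: event extrema; the sign of the deflection gives the class.
    # Prominence (not absolute height) because events ride each other's decays.
    extrema = []    # (index, sign, amplitude)
    for sign in (-1.0, +1.0):
        peaks, props = _signal.find_peaks(sign * y, prominence=height,
                                          distance=dist)
        inside = peaks >= start
        for pk, prom in zip(peaks[inside], props["prominences"][inside]):
            extrema.append((int(pk), sign, float(prom)))
    extrema.sort()

    # alternation: keep the larger of two consecutive same-sign events
    kept: list[tuple[int, float, float]] = []
    for ev in extrema:
        if kept and kept[-1][1] == ev[1]:
            drop = ev if ev[2] <= kept[-1][2] else kept[-1]
            log.warning("two consecutive %s events; dropping the smaller "
                        "(%.1f pA at %.2f ms)",
                        "EPSC" if ev[1] < 0 else "IPSC", drop[2], drop[0] * dt)
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)

    # stage 2: onsets as slope steps. A PSC kernel's slope jumps at its
    # onset, so a matched step detector on the first derivative -- forward
    # short-window mean minus backward short-window mean -- spikes exactly at
    # the onset (negative for EPSCs, positive for IPSCs) while suppressing
    # the smooth slope changes of neighbouring events' peaks and decays.
    slope = np.gradient(y) / dt
    w = max(2, int(round(config.step_window_ms / dt)))
    cs = np.concatenate([[0.0], np.cumsum(slope)])
    step = np.zeros_like(slope)
    idx = np.arange(w + 1, slope.size - w)
    step[idx] = ((cs[idx + w + 1] - cs[idx + 1])
                 - (cs[idx] - cs[idx - w])) / w
    step_scale = float(np.max(np.abs(step[start:]))) if step[start:].size \
        else 0.0
    guard = max(1, int(round(config.onset_guard_ms / dt)))
    onset_events: list[tuple[float, float, float]] = []
    prev_onset_idx: int | None = None
    for pk, sign, amp in kept:
        lo = start if prev_onset_idx is None else max(start,
                                                      prev_onset_idx + guard)
        if lo >= pk:
            lo = max(start, pk - guard)
        seg = sign * step[lo:pk + 1]        # the onset step scores positive
        best = int(np.argmax(seg))
        onset, s_val = refine_extremum(step, lo + best, dt,
                                       mode="min" if sign < 0 else "max")
        # a genuine PSC onset is a sharp interior slope-step peak; a mere
        # return toward baseline between two same-sign events leaves only a
        # window-edge tail or a weak step
        if (best in (0, len(seg) - 1)
                or abs(s_val) < _ONSET_STEP_FRAC * step_scale):
            log.warning("extremum at %.2f ms lacks an onset slope step; "
                        "dropped", pk * dt)
            continue
        onset_events.append((onset, sign, amp))
        prev_onset_idx = int(round(onset / dt))

    # stage-2 drops can leave same-class neighbours; enforce alternation again
    final: list[tuple[float, float, float]] = []
    for ev in onset_events:
        if final and final[-1][1] == ev[1]:
            log.warning("two consecutive %s events after onset validation; "
                        "dropping the smaller",
                        "EPSC" if ev[1] < 0 else "IPSC")
            if ev[2] > final[-1][2]:
                final[-1] = ev
        else:
            final.append(ev)
    epsc = [(t_, a) for t_, s, a in final if s < 0]
    ipsc = [(t_, a) for t_, s, a in final if s > 0]
    return EISequence(
        epsc_onsets=np.array([t_ for t_, _ in epsc]),
        ipsc_onsets=np.array([t_ for t_, _ in ipsc]),
        epsc_amplitudes=np.array([a for _, a in epsc]),
        ipsc_amplitudes=np.array([a for _, a in ipsc]),
    )


def net_charge(t: Trace, window: tuple[float, float],
               protocol: StimulusProtocol | None = None,
               config: EIConfig | None = None) -> float:
    """Net charge transfer (pA*ms) over a window of a baseline-subtracted VC
    trace; negative values indicate a net excitatory response."""
    config = config or EIConfig()
    lo, hi = window
    times = t.times_ms
    m = (times >= lo) & (times <= hi)
    if not np.any(m):
        raise ValidationError("empty integration window")
    if protocol is not None:
        base = float(np.mean(_baseline(t, protocol, config)))
    else:
        base = float(np.median(t.samples[times < lo])) if np.any(times < lo) else 0.0
    return float(np.trapezoid(t.samples[m] - base, times[m]))


def trough_epsc_regression(trough_times, epsc_onsets):
    """OLS of EPSC onset times on ripplet trough times: (slope, intercept, R^2).

    A slope of 1 with high R^2 means the extracellular troughs and the
    intracellular EPSC onsets are the same population event.
    """
    x = np.asarray(trough_times, float)
    y = np.asarray(epsc_onsets, float)
    if x.size != y.size:
        raise ValidationError("paired lists must have equal length")
    if x.size < 2:
        raise ValidationError("need at least two pairs")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in trough times")
    res = _stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
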