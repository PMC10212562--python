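"""Phase assignment of spikes to ripplet cycles or E-I cycles.

Anchors are alternating landmark times carrying unwrapped phases in 180
degree steps: in LFP mode troughs are 0 mod 360 and ripplet peaks +/-180
mod 360; in E-I mode EPSC onsets are 0 mod 360 and IPSC onsets 180 mod 360.
A spike's phase is linearly interpolated between its bracketing anchors and
re-expressed relative to the trough of its half-cycle, giving the printed
-180..+180 scale (slightly beyond +180 for spikes marginally past a final
peak, which are extrapolated on the last half-cycle). Summary statistics are
medians and 10-90th percentiles on this linear (unwrapped) scale, matching
how the phase plots are drawn; circular statistics are deliberately not used
because the printed scale runs past +180.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError, get_logger

__all__ = [
    "PhaseAnchors",
    "PhaseSummary",
    "anchors_from_lfp",
    "anchors_from_ei",
    "assign_phase",
    "phase_to_time",
    "phase_summary",
]

log = get_logger(__name__)

# spikes up to this fraction of the last half-cycle past the final anchor are
# extrapolated rather than excluded (the printed phase scale reaches ~190 deg)
_EXTRAPOLATION_FRAC = 0.25


@dataclass
class PhaseAnchors:
    """Strictly increasing anchor times with unwrapped phases in 180 deg steps.

    Anchors whose unwrapped phase is 0 mod 360 are cycle references (troughs
    or EPSC onsets); phases 180 mod 360 are the antiphase landmarks (ripplet
    peaks or IPSC onsets).
    """

    anchor_times: np.ndarray
    anchor_phases: np.ndarray

    def __post_init__(self) -> None:
        self.anchor_times = np.asarray(self.anchor_times, float)
        self.anchor_phases = np.asarray(self.anchor_phases, float)
        if self.anchor_times.size < 2:
            raise ValidationError("need at least 2 anchors")
        if not np.all(np.diff(self.anchor_times) > 0):
            raise ValidationError("anchor times must be strictly increasing")
        if not np.allclose(np.diff(self.anchor_phases), 180.0):
            raise ValidationError("consecutive anchors must differ by 180 degrees")


@dataclass
class PhaseSummary:
    median_deg: float
    p10_deg: float
    p90_deg: float
    n: int

    def to_dict(self) -> dict:
        return {"median_deg": self.median_deg, "p10_deg": self.p10_deg,
                "p90_deg": self.p90_deg, "n": self.n}


def _interleaved_anchors(zeros: np.ndarray, one_eighties: np.ndarray
                         ) -> PhaseAnchors:
    zeros = np.sort(np.asarray(zeros, float))
    one_eighties = np.sort(np.asarray(one_eighties, float))
    times = np.concatenate([zeros, one_eighties])
    is_zero = np.concatenate([np.ones(zeros.size, bool),
                              np.zeros(one_eighties.size, bool)])
    order = np.argsort(times)
    times, is_zero = times[order], is_zero[order]
    if np.any(np.diff(is_zero.astype(int)) == 0):
        raise ValidationError("anchor classes must strictly interleave")
    # unwrapped phases: 180*k + offset chosen so zero-class anchors are 0 mod 360
    phases = 180.0 * np.arange(times.size)
    offset = -phases[np.flatnonzero(is_zero)[0]] % 360.0
    phases = phases + (offset if offset <= 180 else offset - 360.0)
    return PhaseAnchors(anchor_times=times, anchor_phases=phases)


def anchors_from_lfp(f) -> PhaseAnchors:
    """Anchors from detected ripplet features: troughs 0 deg, peaks +/-180."""
    return _interleaved_anchors(np.asarray(f.trough_times, float),
                                np.asarray(f.transient_times, float))


def anchors_from_ei(e) -> PhaseAnchors:
    """Anchors from an E-I sequence: EPSC onsets 0 deg, IPSC onsets 180."""
    return _interleaved_anchors(np.asarray(e.epsc_onsets, float),
                                np.asarray(e.ipsc_onsets, float))


def assign_phase(spike_times, a: PhaseAnchors) -> np.ndarray:
    """Phase angle of each spike, degrees on the -180..~+190 printed scale.

    Phases are interpolated linearly on the unwrapped scale between the
    bracketing anchors, then re-expressed relative to the nearest cycle
    reference (trough / EPSC onset). Spikes before the first anchor, or more
    than a quarter half-cycle past the last, are excluded (count logged).
    """
    spike_times = np.asarray(spike_times, float)
    t0, t1 = a.anchor_times[0], a.anchor_times[-1]
    last_half = a.anchor_times[-1] - a.anchor_times[-2]
    hi = t1 + _EXTRAPOLATION_FRAC * last_half
    keep = (spike_times >= t0) & (spike_times <= hi)
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        log.info("%d spike(s) outside the anchor span excluded", n_excluded)
    kept = spike_times[keep]
    # linear interpolation on the unwrapped scale (extrapolates the last segment)
    slope_last = 180.0 / last_half
    unwrapped = np.interp(kept, a.anchor_times, a.anchor_phases)
    past = kept > t1
    unwrapped[past] = a.anchor_phases[-1] + (kept[past] - t1) * slope_last
    # re-express relative to the trough of the spike's own half-cycle:
    # the nearest multiple of 360 at or below the bracketing pair
    rel = unwrapped - 360.0 * np.round(unwrapped / 360.0)
    beyond = unwrapped > a.anchor_phases[-1]
    if np.any(beyond) and a.anchor_phases[-1] % 360.0 == 180.0:
        # past a final peak there is no following trough: keep the phase
        # referenced to the preceding trough (can slightly exceed +180)
        rel[beyond] = 180.0 + (unwrapped[beyond] - a.anchor_phases[-1])
    return rel


def phase_to_time(angle_deg: float, period_ms: float) -> float:
    """Convert a phase angle to time: (angle/360) x period."""
    if period_ms <= 0:
        raise ValidationError("period must be > 0")
    return angle_deg / 360.0 * period_ms


def phase_summary(angles_deg) -> PhaseSummary:
    """Median and 10-90th percentiles on the linear phase scale."""
    angles = np.asarray(angles_deg, float)
    if angles.size < 1:
        raise ValidationError("need at least one phase angle")
    p10, med, p90 = np.percentile(angles, [10, 50, 90])
    return PhaseSummary(float(med), float(p10), float(p90), int(angles.size))
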