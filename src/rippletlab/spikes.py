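"""Spike detection, burst statistics, intrinsic parameters, FS/RS classing.

The central objects are a :class:`SpikeTrainSet` (per-trial spike peak times
with per-spike order assignments) and the derived :class:`BurstStats`:
per-order mean latency, across-trial jitter (SD of peak times), coefficient
of variation (CV = SD/mean), ISIs between order means, and the burst
frequency defined as the reciprocal of the mean ISI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .core import SweepSet, Trace, ValidationError, get_logger
from .dsp import parabolic_peak_time

__all__ = [
    "SpikeConfig",
    "SpikeTrainSet",
    "BurstStats",
    "EphysParams",
    "detect_spikes",
    "detect_spike_trains",
    "assign_spike_orders",
    "burst_stats",
    "burst_frequency_from_isis",
    "extract_ephys_params",
    "classify_cell",
    "coupling_coefficient",
]

log = get_logger(__name__)


@dataclass(frozen=True)
class SpikeConfig:
    detection_level_mv: float = 0.0     # spike peaks must exceed this
    min_separation_ms: float = 0.8      # refractory merge
    order_tolerance_ms: float = 0.8     # template matching window


@dataclass
class SpikeTrainSet:
    """Per-trial spike peak times plus (optional) per-spike order labels."""

    trains: list[np.ndarray]                    # ms, strictly increasing per trial
    orders: list[np.ndarray] | None = None      # int order (1-based) or -1 unassigned

    def __post_init__(self) -> None:
        self.trains = [np.asarray(tr, float) for tr in self.trains]
        for tr in self.trains:
            if tr.size > 1 and not np.all(np.diff(tr) > 0):
                raise ValidationError("spike times must increase within a trial")
        if self.orders is not None:
            self.orders = [np.asarray(o, int) for o in self.orders]

    @property
    def n_trials(self) -> int:
        return len(self.trains)


@dataclass
class BurstStats:
    """Per-order burst statistics for one cell's sweep set."""

    order_means_ms: np.ndarray
    order_jitters_us: np.ndarray       # SD of peak times; NaN where <2 trials
    order_cvs_pct: np.ndarray          # 100 * jitter / mean
    order_reliability: np.ndarray      # fraction of trials with that order
    isis_ms: np.ndarray                # between consecutive order means
    burst_frequency_hz: float | None   # 1000 / mean(ISI)
    spikes_per_stimulus: float

    def to_dict(self) -> dict:
        return {
            "order_means_ms": list(map(float, self.order_means_ms)),
            "order_jitters_us": list(map(float, self.order_jitters_us)),
            "order_cvs_pct": list(map(float, self.order_cvs_pct)),
            "order_reliability": list(map(float, self.order_reliability)),
            "isis_ms": list(map(float, self.isis_ms)),
            "burst_frequency_hz": self.burst_frequency_hz,
            "spikes_per_stimulus": self.spikes_per_stimulus,
        }


@dataclass
class EphysParams:
    """Eight intrinsic electrophysiological parameters of one cell."""

    v_rest: float          # mV, pre-step baseline with no holding current
    v_threshold: float     # mV, where dV/dt reaches 5 V/s on the rheobase spike
    spike_height: float    # mV, peak - threshold
    swhh: float            # ms, width at half height between threshold and peak
    ahp: float             # mV, threshold - post-spike trough
    r_in: float            # MOhm, I-V slope over subthreshold steps (|dV|<=15 mV)
    i_max: float           # pA, largest step before >10% first-spike height drop
    f_max: float           # Hz, 1000/mean(last five ISIs) at i_max

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# Detection and order assignment
# ---------------------------------------------------------------------------

def detect_spikes(t: Trace, config: SpikeConfig | None = None) -> np.ndarray:
    """Spike peak times (ms, sub-sample) in a current-clamp sweep.

    Local maxima above the detection level with at least the refractory
    separation; closer pairs are merged to the larger peak (logged).
    """
    if t.kind != "current_clamp":
        raise ValidationError("spike detection expects a current-clamp trace")
    config = config or SpikeConfig()
    y = t.samples
    dist = max(1, int(round(config.min_separation_ms / t.dt_ms)))
    peaks, props = _signal.find_peaks(y, height=config.detection_level_mv)
    if peaks.size == 0:
        return np.array([])
    # refractory merge: keep the larger of any pair closer than the separation
    kept: list[int] = []
    for idx in peaks:
        if kept and (idx - kept[-1]) < dist:
            log.warning("spikes %.2f and %.2f ms closer than %.1f ms; merged",
                        kept[-1] * t.dt_ms, idx * t.dt_ms,
                        config.min_separation_ms)
            if y[idx] > y[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return np.array([parabolic_peak_time(y, i, t.dt_ms)[0] for i in kept])


def detect_spike_trains(s: SweepSet, config: SpikeConfig | None = None
                        ) -> SpikeTrainSet:
    """Detect spikes on every sweep of a current-clamp set."""
    return SpikeTrainSet([detect_spikes(sw, config) for sw in s.sweeps])


def _match_to_template(train: np.ndarray, template: np.ndarray,
                       tol: float) -> np.ndarray:
    """Nearest-order assignment within tolerance, unique and time-ordered."""
    orders = np.full(train.size, -1, int)
    if template.size == 0:
        return orders
    for i, ts in enumerate(train):
        k = int(np.argmin(np.abs(template - ts)))
        if abs(template[k] - ts) <= tol:
            orders[i] = k + 1
    # resolve duplicates: keep the closest spike per order
    for k in np.unique(orders[orders > 0]):
        idxs = np.flatnonzero(orders == k)
        if idxs.size > 1:
            best = idxs[np.argmin(np.abs(train[idxs] - template[k - 1]))]
            orders[np.setdiff1d(idxs, [best])] = -1
    return orders


def assign_spike_orders(s: SpikeTrainSet,
                        config: SpikeConfig | None = None) -> SpikeTrainSet:
    """Assign each spike an across-trial order (1-based).

    The template is the per-order median time over the trials with the modal
    spike count; spikes are matched to the nearest template order within
    tolerance, the template is re-estimated once from all assignments, and
    matching is repeated. Unmatched spikes stay unassigned (-1).
    """
    if s.n_trials < 3:
        raise ValidationError("order assignment needs >= 3 trials")
    config = config or SpikeConfig()
    counts = np.array([tr.size for tr in s.trains])
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        raise ValidationError("no spikes in any trial")
    modal = np.bincount(nonzero).argmax()
    modal_trials = [tr for tr in s.trains if tr.size == modal]
    if len(modal_trials) < 2:
        raise ValidationError("no modal-spike-count trial group of size >= 2")
    template = np.median(np.stack(modal_trials), axis=0)

    for _ in range(2):   # initial match + one re-estimation
        orders = [_match_to_template(tr, template, config.order_tolerance_ms)
                  for tr in s.trains]
        new_template = []
        for k in range(1, template.size + 1):
            times = [tr[o == k][0] for tr, o in zip(s.trains, orders)
                     if np.any(o == k)]
            new_template.append(np.median(times) if times else template[k - 1])
        template = np.asarray(new_template)
    return SpikeTrainSet(trains=s.trains, orders=orders)


# ---------------------------------------------------------------------------
# Burst statistics
# ---------------------------------------------------------------------------

def burst_frequency_from_isis(isis_ms) -> float:
    """Burst frequency = 1 / mean ISI, in Hz."""
    isis_ms = np.asarray(isis_ms, float)
    if isis_ms.size == 0:
        raise ValidationError("need at least one ISI")
    return 1000.0 / float(np.mean(isis_ms))


def burst_stats(s: SpikeTrainSet) -> BurstStats:
    """Per-order latency/jitter/CV/reliability and the burst frequency.

    Jitter uses only trials where the order fired (failures excluded) with
    the n-1 SD; orders present in fewer than two trials get NaN jitter.
    """
    if s.orders is None:
        raise ValidationError("orders must be assigned first")
    n_orders = max((int(o.max()) for o in s.orders if o.size and o.max() > 0),
                   default=0)
    if n_orders == 0:
        raise ValidationError("no assigned spikes")
    means, jitters, cvs, rel = [], [], [], []
    for k in range(1, n_orders + 1):
        times = np.array([tr[o == k][0] for tr, o in zip(s.trains, s.orders)
                          if np.any(o == k)])
        means.append(times.mean())
        rel.append(times.size / s.n_trials)
        if times.size >= 2:
            sd_ms = times.std(ddof=1)
            jitters.append(sd_ms * 1000.0)
            cvs.append(100.0 * sd_ms / times.mean())
        else:
            log.warning("order %d present in <2 trials; jitter undefined", k)
            jitters.append(np.nan)
            cvs.append(np.nan)
    means = np.asarray(means)
    isis = np.diff(means)
    freq = burst_frequency_from_isis(isis) if isis.size else None
    spikes_per_stim = float(np.mean([tr.size for tr in s.trains]))
    return BurstStats(means, np.asarray(jitters), np.asarray(cvs),
                      np.asarray(rel), isis, freq, spikes_per_stim)


# ---------------------------------------------------------------------------
# Intrinsic-parameter extraction and classification
# ---------------------------------------------------------------------------

_DVDT_THRESHOLD = 5.0   # mV/ms (= 5 V/s)


def _threshold_crossing(v: np.ndarray, peak_idx: int, rate: float
                        ) -> tuple[float, int]:
    """Voltage and index where dV/dt first sustains 5 V/s before a peak."""
    dvdt = np.gradient(v) * rate / 1000.0   # mV/ms
    i = peak_idx
    while i > 0 and dvdt[i] < _DVDT_THRESHOLD:   # skip the near-peak rolloff
        i -= 1
    if i == 0:
        raise ValidationError("dV/dt never reaches 5 V/s; threshold undefined")
    while i > 0 and dvdt[i] >= _DVDT_THRESHOLD:
        i -= 1
    # linear interpolation of the crossing between samples i and i+1
    lo, hi = dvdt[i], dvdt[i + 1]
    frac = 0.0 if hi == lo else (_DVDT_THRESHOLD - lo) / (hi - lo)
    v_th = v[i] + frac * (v[i + 1] - v[i])
    return float(v_th), i + 1


def _first_spike_metrics(v: np.ndarray, rate: float, step_on_idx: int):
    """Threshold, height, half-width and AHP of the first spike in a sweep."""
    dt_ms = 1000.0 / rate
    peaks, _ = _signal.find_peaks(v, height=0.0)
    peaks = peaks[peaks > step_on_idx]
    if peaks.size == 0:
        return None
    pk = peaks[0]
    v_th, th_idx = _threshold_crossing(v, pk, rate)
    _, v_peak = parabolic_peak_time(v, pk, dt_ms)
    height = v_peak - v_th
    half = v_th + height / 2.0
    i = pk
    while i > 0 and v[i] > half:
        i -= 1
    t_up = (i + (half - v[i]) / (v[i + 1] - v[i])) * dt_ms
    j = pk
    while j < len(v) - 1 and v[j] > half:
        j += 1
    t_down = (j - 1 + (v[j - 1] - half) / (v[j - 1] - v[j])) * dt_ms
    swhh = t_down - t_up
    after = v[pk:min(pk + int(6.0 / dt_ms), len(v))]
    ahp = v_th - float(after.min())
    return {"v_th": v_th, "peak": float(v_peak), "height": float(height),
            "swhh": float(swhh), "ahp": float(ahp), "peak_idx": int(pk)}


def _spike_times_in(v: np.ndarray, rate: float, step_on_idx: int) -> np.ndarray:
    tr = Trace(v, rate=rate, kind="current_clamp")
    times = detect_spikes(tr, SpikeConfig(detection_level_mv=0.0))
    return times[times > step_on_idx / rate * 1000.0]


def extract_ephys_params(step_sweeps: SweepSet) -> EphysParams:
    """Extract the eight intrinsic parameters from a 600 ms current-step family.

    The sweep set's labels must carry ``step_pa`` (semicolon-separated pA per
    sweep), ``step_onset_ms`` and ``step_duration_ms``. Input resistance is
    the least-squares I-V slope over subthreshold steps within +/-15 mV of
    rest; Imax is the largest step before the first-spike height drops more
    than 10% below its rheobase value; Fmax is the reciprocal of the mean of
    the last five ISIs at Imax.
    """
    labels = step_sweeps.labels
    try:
        currents = np.array([float(x) for x in labels["step_pa"].split(";")])
        step_on = float(labels["step_onset_ms"])
        step_ms = float(labels["step_duration_ms"])
    except KeyError as exc:
        raise ValidationError(f"step family missing label {exc}") from None
    if currents.size != step_sweeps.n_sweeps:
        raise ValidationError("step_pa length must match sweep count")
    rate = step_sweeps.rate
    on_idx = int(step_on * rate / 1000.0)
    off_idx = int((step_on + step_ms) * rate / 1000.0)
    ss_lo = on_idx + (off_idx - on_idx) // 2      # steady state: last half of step

    base = np.mean([sw.samples[:on_idx].mean() for sw in step_sweeps.sweeps])
    spikes_per_sweep = [
        _spike_times_in(sw.samples, rate, on_idx) for sw in step_sweeps.sweeps]

    # input resistance from subthreshold steps
    iv_i, iv_dv = [], []
    for i_pa, sw, spk in zip(currents, step_sweeps.sweeps, spikes_per_sweep):
        if spk.size or i_pa == 0:
            continue
        dv = sw.samples[ss_lo:off_idx].mean() - base
        if abs(dv) <= 15.0:
            iv_i.append(i_pa)
            iv_dv.append(dv)
    if len(iv_i) < 2:
        raise ValidationError("need >= 2 subthreshold steps for input resistance")
    slope = np.polyfit(iv_i, iv_dv, 1)[0]          # mV per pA
    r_in = slope * 1000.0                          # MOhm

    supra = [(i_pa, sw) for i_pa, sw, spk in
             zip(currents, step_sweeps.sweeps, spikes_per_sweep)
             if i_pa > 0 and spk.size > 0]
    if not supra:
        raise ValidationError("no spiking step; parameter set is non-spiking")
    supra.sort(key=lambda x: x[0])
    rheo_i, rheo_sw = supra[0]
    rheo = _first_spike_metrics(rheo_sw.samples, rate, on_idx)
    if rheo is None:
        raise ValidationError("rheobase sweep has no detectable spike")

    i_max = rheo_i
    for i_pa, sw in supra:
        m = _first_spike_metrics(sw.samples, rate, on_idx)
        if m is None:
            continue
        if m["height"] < 0.9 * rheo["height"]:
            break
        i_max = i_pa
    f_sweep = next(sw for i_pa, sw in supra if i_pa == i_max)
    isis = np.diff(_spike_times_in(f_sweep.samples, rate, on_idx))
    if isis.size == 0:
        raise ValidationError("Imax sweep has a single spike; Fmax undefined")
    f_max = 1000.0 / float(np.mean(isis[-5:]))

    return EphysParams(
        v_rest=float(base), v_threshold=rheo["v_th"],
        spike_height=rheo["height"], swhh=rheo["swhh"], ahp=rheo["ahp"],
        r_in=float(r_in), i_max=float(i_max), f_max=f_max,
    )


def classify_cell(p: EphysParams) -> str:
    """Threshold rule separating fast-spiking from regular-spiking cells.

    FS cells sustain 150-300 Hz steady firing with narrow spikes; RS cells
    fire below ~50 Hz steady state with broader spikes. Cells in the gap are
    left unclassified.
    """
    if p.f_max >= 150.0 and p.swhh <= 0.5:
        return "FS"
    if p.f_max < 100.0 and p.swhh > 0.5:
        return "RS"
    return "unclassified"


def coupling_coefficient(pre_step: Trace, post_response: Trace,
                         step_window: tuple[float, float]) -> float:
    """Electrical-coupling coefficient, percent.

    100 x (steady-state voltage deflection in the follower) / (deflection in
    the driver) during a hyperpolarizing step; steady state is the mean over
    the last half of the step window minus the pre-step baseline.
    """
    if pre_step.kind != "current_clamp" or post_response.kind != "current_clamp":
        raise ValidationError("coupling test expects current-clamp traces")
    lo, hi = step_window
    mid = (lo + hi) / 2.0

    def _delta(tr: Trace) -> float:
        t = tr.times_ms
        baseline = tr.samples[t < lo].mean()
        steady = tr.samples[(t >= mid) & (t < hi)].mean()
        return float(steady - baseline)

    dv_pre = _delta(pre_step)
    if abs(dv_pre) < 1.0:
        raise ValidationError("driver deflection < 1 mV; coefficient undefined")
    return 100.0 * _delta(post_response) / dv_pre
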