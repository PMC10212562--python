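"""Hierarchical synthetic-sweep generator for every modality the pipeline reads.

The generator emulates the statistical structure of an optogenetic
thalamocortical-activation experiment in a barrel-cortex slice:

* population level -- event-time means and SEMs for presynaptic volleys,
  ripplet transients and FS spike orders (the printed cohort statistics);
* slice/cell level -- per-slice (or per-cell) means drawn from
  ``N(population mean, SEM * sqrt(n))``, optionally with a shared slice
  offset so that within-slice event times co-vary;
* trial level -- per-sweep timing jitter, spike failures, and additive
  white noise.

LFP sweeps are an additive model (stimulus artifact + presynaptic volleys +
postsynaptic transients on a slow positive envelope + noise) so that the
pharmacological subtraction logic of the analysis (TTX isolates the artifact,
CNQX+APV the presynaptic component) holds by construction.

All event kernels are evaluated in continuous time at the sample points, so
sub-sample jitters (tens of microseconds at a 50 us sampling period) are
representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_RATE_HZ,
    DEFAULT_SWEEP_MS,
    StimulusProtocol,
    SweepSet,
    Trace,
    ValidationError,
)

__all__ = [
    "PopulationParams",
    "SliceSpec",
    "RealizedCell",
    "draw_slices",
    "draw_cells",
    "synth_lfp_sweeps",
    "lfp_component_traces",
    "synth_current_clamp_sweeps",
    "synth_voltage_clamp_sweeps",
    "synth_pair_trains",
    "synth_step_family",
    "trough_times_for_slice",
]


# ---------------------------------------------------------------------------
# Population-level parameters (printed cohort statistics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Cohort means/SEMs of event times plus kernel and noise defaults.

    SEMs are converted to between-slice (or between-cell) SDs as
    ``SEM * sqrt(n)`` with the cohort sizes of the respective datasets
    (8 slices for volleys, 11 for ripplet transients, 25 FS cells).
    """

    presyn_volley_means: tuple[float, ...] = (2.3, 6.0, 10.8)
    presyn_volley_sems: tuple[float, ...] = (0.07, 0.22, 0.24)
    presyn_n: int = 8
    ripplet_peak_means: tuple[float, ...] = (4.4, 6.5, 8.9, 11.9)
    ripplet_peak_sems: tuple[float, ...] = (0.11, 0.26, 0.30, 0.38)
    ripplet_n: int = 11
    fs_spike_means: tuple[float, ...] = (3.1, 5.5, 7.7, 10.3)
    fs_spike_sems: tuple[float, ...] = (0.06, 0.08, 0.12, 0.14)
    fs_n: int = 25
    fs_trial_jitters_us: tuple[float, ...] = (23.0, 63.0, 110.0, 183.0)
    fs_isi_means: tuple[float, ...] = (2.4, 2.2, 2.7)
    fs_isi_sems: tuple[float, ...] = (0.05, 0.08, 0.13)
    fs_phase_deg: tuple[float, float, float] = (26.0, -14.0, 82.0)   # median, p10, p90
    rs_phase_deg: tuple[float, float, float] = (161.0, 145.0, 187.0)
    ei_fs_phase_deg: tuple[float, float, float] = (59.0, 5.0, 106.0)
    # noise SDs per modality
    noise_sd_lfp: float = 0.02      # mV
    noise_sd_cc: float = 0.5        # mV
    noise_sd_vc: float = 5.0        # pA
    # kernel shapes
    volley_sigma_ms: float = 0.25
    transient_sigma_ms: float = 0.35
    epsc_rise_ms: float = 0.2
    epsc_decay_ms: float = 1.0
    ipsc_rise_ms: float = 0.4
    ipsc_decay_ms: float = 2.5

    def __post_init__(self) -> None:
        for means, sems in (
            (self.presyn_volley_means, self.presyn_volley_sems),
            (self.ripplet_peak_means, self.ripplet_peak_sems),
            (self.fs_spike_means, self.fs_spike_sems),
            (self.fs_isi_means, self.fs_isi_sems),
        ):
            if len(means) != len(sems):
                raise ValidationError("SEM list must match its mean list in length")
        for means in (self.presyn_volley_means, self.ripplet_peak_means,
                      self.fs_spike_means):
            if not np.all(np.diff(means) > 0):
                raise ValidationError("event-time means must be strictly increasing")

    def slice_sds(self, which: str) -> np.ndarray:
        """Between-unit SDs = SEM * sqrt(n) for a named event family."""
        table = {
            "presyn": (self.presyn_volley_sems, self.presyn_n),
            "ripplet": (self.ripplet_peak_sems, self.ripplet_n),
            "fs": (self.fs_spike_sems, self.fs_n),
            "isi": (self.fs_isi_sems, self.fs_n),
        }
        sems, n = table[which]
        return np.asarray(sems) * np.sqrt(n)


@dataclass
class SliceSpec:
    """One slice's realized event times (ms from light onset)."""

    volley_times: np.ndarray
    ripplet_times: np.ndarray
    fs_spike_times: np.ndarray
    volley_amps_mv: np.ndarray = field(
        default_factory=lambda: np.array([0.4, 0.2, 0.1]))
    transient_amps_mv: np.ndarray = field(
        default_factory=lambda: np.array([1.2, 1.5, 1.0, 0.7]))


@dataclass
class RealizedCell:
    """One cell's firing program for current/voltage-clamp synthesis."""

    cell_class: str                      # "FS" | "RS"
    mean_times: np.ndarray               # per-order spike peak times, ms from onset
    trial_jitters_ms: np.ndarray         # per-order across-trial SD at high intensity
    reliability: np.ndarray              # per-order firing probability at high intensity
    v_rest: float = -70.0
    spike_peak_mv: float = 25.0
    spike_sigma_ms: float = 0.13
    ei_balance: float = 0.5              # 0 = fully excitatory, 1 = fully inhibitory
    epsp_times: np.ndarray | None = None  # RS subthreshold bumps (defaults to ripplets)

    def __post_init__(self) -> None:
        self.mean_times = np.asarray(self.mean_times, float)
        self.trial_jitters_ms = np.asarray(self.trial_jitters_ms, float)
        self.reliability = np.asarray(self.reliability, float)
        if self.cell_class not in ("FS", "RS"):
            raise ValidationError("cell_class must be FS or RS")
        if np.any((self.reliability < 0) | (self.reliability > 1)):
            raise ValidationError("reliability must lie in [0, 1]")
        if not np.all(np.diff(self.mean_times) > 0):
            raise ValidationError("event times must be strictly increasing")


_RESIDUAL_SD_MS = 0.15


def _draw_family(rng: np.random.Generator, means, sds, correlated: bool):
    """Draw one slice's event-time family with per-order SD = SEM * sqrt(n).

    ``correlated`` draws a shared slice offset plus a shared period-scaling
    factor plus a small independent residual, so later orders inherit the
    larger printed SDs from the slice's overall timing without scrambling
    the within-slice event spacing; ``correlated=False`` draws every order
    independently.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if not correlated or means.size == 1 or np.any(sds == 0):
        return np.sort(means + rng.normal(0.0, 1.0, means.size) * sds)
    delta = means - means[0]
    later = delta > 0
    sb_i = np.sqrt(np.maximum(
        sds[later] ** 2 - sds[0] ** 2 - _RESIDUAL_SD_MS ** 2, 0.0)) / delta[later]
    sigma_b = float(np.median(sb_i)) if sb_i.size else 0.0
    # analyzable slices always show distinguishable events: reject draws whose
    # gaps deviate too far from the mean spacing. The bound is symmetric about
    # the mean gap, so cohort means stay unbiased.
    mean_gaps = np.diff(means)
    dev_max = max(0.3, float(mean_gaps.min()) - 1.7)
    for _ in range(500):
        offset = rng.normal(0.0, sds[0])
        scale = rng.normal(0.0, sigma_b)
        resid = rng.normal(0.0, _RESIDUAL_SD_MS, means.size)
        resid[0] = 0.0
        times = means + offset + scale * delta + resid
        if np.all(np.abs(np.diff(times) - mean_gaps) <= dev_max):
            return times
    return np.sort(times)


def draw_slices(
    p: PopulationParams,
    n_slices: int,
    seed: int,
    correlated: bool = True,
) -> list[SliceSpec]:
    """Draw per-slice event-time means from the population distributions.

    Each family (volleys / ripplet transients / FS spikes) has per-order SD
    equal to ``SEM * sqrt(n)``; see ``_draw_family`` for the correlation
    structure. ``correlated=False`` gives fully independent per-order draws.
    """
    if n_slices < 1:
        raise ValidationError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_slices):
        out.append(SliceSpec(
            volley_times=_draw_family(
                rng, p.presyn_volley_means, p.slice_sds("presyn"), correlated),
            ripplet_times=_draw_family(
                rng, p.ripplet_peak_means, p.slice_sds("ripplet"), correlated),
            fs_spike_times=_draw_family(
                rng, p.fs_spike_means, p.slice_sds("fs"), correlated),
        ))
    return out


def draw_cells(
    p: PopulationParams,
    n_cells: int,
    seed: int,
    cell_class: str = "FS",
    correlated: bool = True,
) -> list[RealizedCell]:
    """Draw per-cell FS (or RS) firing programs from the population stats."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        if cell_class == "FS":
            times = _draw_family(rng, p.fs_spike_means, p.slice_sds("fs"),
                                 correlated)
            cells.append(RealizedCell(
                cell_class="FS",
                mean_times=times,
                trial_jitters_ms=np.asarray(p.fs_trial_jitters_us) / 1000.0,
                reliability=np.array([1.0, 1.0, 1.0, 0.9]),
                v_rest=-70.0,
                spike_peak_mv=25.0,
                spike_sigma_ms=0.13,
                ei_balance=float(rng.uniform(0.2, 0.8)),
            ))
        else:
            # RS cells fire 1-2 spikes riding the first EPSPs of the envelope
            ripplets = _draw_family(rng, p.ripplet_peak_means,
                                    p.slice_sds("ripplet"), correlated)
            cells.append(RealizedCell(
                cell_class="RS",
                mean_times=ripplets[:2] - 0.1,
                trial_jitters_ms=np.array([0.10, 0.25]),
                reliability=np.array([0.9, 0.35]),
                v_rest=-75.0,
                spike_peak_mv=30.0,
                spike_sigma_ms=0.26,
                ei_balance=float(rng.uniform(0.0, 1.0)),
                epsp_times=ripplets,
            ))
    return cells


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _gaussian(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _half_cosine(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    x = (t - start) / duration
    out = np.zeros_like(t)
    m = (x >= 0) & (x <= 1)
    out[m] = np.sin(np.pi * x[m])
    return out


def _diff_exp(t: np.ndarray, onset: float, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials PSC kernel, normalized to unit peak."""
    x = t - onset
    out = np.zeros_like(t)
    m = x > 0
    out[m] = np.exp(-x[m] / decay) - np.exp(-x[m] / rise)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return out / peak


def _time_axis(protocol: StimulusProtocol, rate: float, sweep_ms: float):
    n = int(round(sweep_ms * rate / 1000.0))
    return np.arange(n) / rate * 1000.0


# ---------------------------------------------------------------------------
# LFP sweeps
# ---------------------------------------------------------------------------

_ARTIFACT_MV = -0.08
_ENVELOPE_MV = 0.35
_ENVELOPE_MS = 12.0
# per-order trial jitter of event times grows with order ("decreasing
# amplitude and coherence" of late events)
_VOLLEY_TRIAL_JITTER = np.array([0.02, 0.10, 0.15])
_TRANSIENT_TRIAL_JITTER = np.array([0.03, 0.06, 0.10, 0.15])


def lfp_component_traces(
    slice_spec: SliceSpec,
    protocol: StimulusProtocol,
    n_sweeps: int,
    seed: int,
    p: PopulationParams | None = None,
    rate: float = DEFAULT_RATE_HZ,
    sweep_ms: float = DEFAULT_SWEEP_MS,
) -> dict[str, np.ndarray]:
    """Noise-free per-sweep component arrays (artifact/presyn/postsyn).

    The same seed yields identical per-sweep event jitters regardless of
    which components a condition includes, so
    ``control = artifact + presynaptic + postsynaptic`` holds exactly
    before noise injection.
    """
    p = p or PopulationParams()
    t = _time_axis(protocol, rate, sweep_ms)
    onset = protocol.onset
    rng = np.random.default_rng([seed, 101])

    n_volleys = len(slice_spec.volley_times) if protocol.duration >= 5.0 else 1
    artifact = np.zeros((n_sweeps, t.size))
    presyn = np.zeros_like(artifact)
    postsyn = np.zeros_like(artifact)

    pulse = (t >= onset) & (t < onset + protocol.duration)
    transient_amps = slice_spec.transient_amps_mv.copy()
    if protocol.duration <= 1.0:
        transient_amps = transient_amps.copy()
        transient_amps[-1] *= 0.4    # 1 ms pulses barely recruit the last transient

    for i in range(n_sweeps):
        artifact[i, pulse] = _ARTIFACT_MV
        for k in range(n_volleys):
            mu = onset + slice_spec.volley_times[k] + rng.normal(
                0.0, _VOLLEY_TRIAL_JITTER[min(k, len(_VOLLEY_TRIAL_JITTER) - 1)])
            presyn[i] -= slice_spec.volley_amps_mv[k] * _gaussian(
                t, mu, p.volley_sigma_ms)
        env_start = onset + slice_spec.ripplet_times[0] - 2.0
        postsyn[i] += _ENVELOPE_MV * _half_cosine(t, env_start, _ENVELOPE_MS)
        for k, t_k in enumerate(slice_spec.ripplet_times):
            mu = onset + t_k + rng.normal(
                0.0, _TRANSIENT_TRIAL_JITTER[min(k, len(_TRANSIENT_TRIAL_JITTER) - 1)])
            postsyn[i] -= transient_amps[min(k, len(transient_amps) - 1)] * _gaussian(
                t, mu, p.transient_sigma_ms)
    return {"artifact": artifact, "presynaptic": presyn, "postsynaptic": postsyn}


def synth_lfp_sweeps(
    slice_spec: SliceSpec,
    protocol: StimulusProtocol,
    condition: str,
    n_sweeps: int,
    seed: int,
    p: PopulationParams | None = None,
    rate: float = DEFAULT_RATE_HZ,
    sweep_ms: float = DEFAULT_SWEEP_MS,
    noise_sd: float | None = None,
) -> SweepSet:
    """Synthesize LFP sweeps under one pharmacological condition.

    ``ttx`` leaves only the stimulus artifact; ``cnqx_apv`` adds the
    presynaptic volleys; ``control`` adds the postsynaptic ripplet
    transients riding on a slow positive envelope.
    """
    if condition not in ("control", "cnqx_apv", "ttx"):
        raise ValidationError(f"unsupported LFP condition {condition!r}")
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    p = p or PopulationParams()
    noise_sd = p.noise_sd_lfp if noise_sd is None else noise_sd
    comp = lfp_component_traces(slice_spec, protocol, n_sweeps, seed, p,
                                rate, sweep_ms)
    data = comp["artifact"].copy()
    if condition in ("cnqx_apv", "control"):
        data += comp["presynaptic"]
    if condition == "control":
        data += comp["postsynaptic"]
    rng = np.random.default_rng([seed, 202, ("control", "cnqx_apv", "ttx").index(condition)])
    data = data + rng.normal(0.0, noise_sd, data.shape)
    sweeps = [Trace(row, rate=rate, kind="lfp") for row in data]
    return SweepSet(sweeps=sweeps, protocol=protocol, condition=condition)


# ---------------------------------------------------------------------------
# Current-clamp sweeps
# ---------------------------------------------------------------------------

def _jitter_scale(intensity: float) -> float:
    """Spike-time jitter grows at low light intensity (~2.5x at 20%)."""
    return max(1.0, (0.9 / intensity) ** 0.6)


def _order_reliability(base: float, order_idx: int, intensity: float) -> float:
    """Late spike orders lose reliability at low intensity; the first does not."""
    fade = (0.9 - min(intensity, 0.9)) / 0.8
    return float(base * np.clip(1.0 - 0.18 * order_idx * fade, 0.05, 1.0))


def _spike_waveform(t, mu, amp, sigma):
    # stylized spike: Gaussian depolarization + small after-hyperpolarization
    return amp * _gaussian(t, mu, sigma) - 0.08 * amp * _gaussian(t, mu + 1.0, 0.6)


def synth_current_clamp_sweeps(
    cell: RealizedCell,
    protocol: StimulusProtocol,
    n_sweeps: int,
    seed: int,
    p: PopulationParams | None = None,
    rate: float = DEFAULT_RATE_HZ,
    sweep_ms: float = DEFAULT_SWEEP_MS,
    noise_sd: float | None = None,
) -> SweepSet:
    """Current-clamp sweeps: a depolarizing envelope carrying a precisely
    timed spike burst (FS) or EPSP bumps with 1-2 spikes (RS).

    Trial jitter and spike failures scale with stimulus intensity; RS spikes
    "hop" to the second EPSP at low intensity when the first fails.
    """
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    p = p or PopulationParams()
    noise_sd = p.noise_sd_cc if noise_sd is None else noise_sd
    t = _time_axis(protocol, rate, sweep_ms)
    onset = protocol.onset
    rng = np.random.default_rng([seed, 303])
    jscale = _jitter_scale(protocol.intensity)
    amp = cell.spike_peak_mv - cell.v_rest

    rows = np.full((n_sweeps, t.size), cell.v_rest, float)
    env_amp = 10.0 if cell.cell_class == "FS" else 15.0
    for i in range(n_sweeps):
        v = rows[i]
        v += env_amp * protocol.intensity * _half_cosine(t, onset + 1.0, 30.0)
        if cell.cell_class == "RS":
            epsps = cell.epsp_times if cell.epsp_times is not None \
                else np.asarray(p.ripplet_peak_means)
            for te in epsps:
                v += 4.0 * _gaussian(t, onset + te, 0.6)
        fired_first = True
        for k, mean_t in enumerate(cell.mean_times):
            rel = _order_reliability(cell.reliability[k], k, protocol.intensity)
            fired = rng.random() < rel
            mu = onset + mean_t + rng.normal(0.0, cell.trial_jitters_ms[k] * jscale)
            if cell.cell_class == "RS" and k == 1 and not fired_first:
                fired = True    # EPSP hopping: the spike moves to the 2nd EPSP
            if fired:
                v += _spike_waveform(t, mu, amp, cell.spike_sigma_ms)
            elif cell.cell_class == "FS":
                # a failed spike reveals the underlying EPSP
                v += 4.0 * _gaussian(t, mu, 0.6)
            if k == 0:
                fired_first = fired
    rows += np.random.default_rng([seed, 304]).normal(0.0, noise_sd, rows.shape)
    sweeps = [Trace(row, rate=rate, kind="current_clamp") for row in rows]
    return SweepSet(sweeps=sweeps, protocol=protocol, condition="control",
                    labels={"cell_class": cell.cell_class})


# ---------------------------------------------------------------------------
# Voltage-clamp sweeps
# ---------------------------------------------------------------------------

def trough_times_for_slice(slice_spec: SliceSpec) -> np.ndarray:
    """Ripplet trough times implied by a slice's transient times.

    Troughs are the positive maxima between consecutive transients, plus the
    leading trough half a period before the first transient (trough count =
    transient count + 1 would include the final one; EPSC onsets align with
    the troughs *preceding* each transient, so this returns leading trough +
    the inter-transient midpoints).
    """
    peaks = slice_spec.ripplet_times
    mids = (peaks[:-1] + peaks[1:]) / 2.0
    half = np.median(np.diff(peaks)) / 2.0
    return np.concatenate([[peaks[0] - half], mids])


def synth_voltage_clamp_sweeps(
    cell: RealizedCell,
    protocol: StimulusProtocol,
    n_sweeps: int,
    seed: int,
    slice_spec: SliceSpec | None = None,
    holding: float = -52.0,
    p: PopulationParams | None = None,
    rate: float = DEFAULT_RATE_HZ,
    sweep_ms: float = DEFAULT_SWEEP_MS,
    noise_sd: float | None = None,
) -> SweepSet:
    """Voltage-clamp sweeps with alternating EPSC/IPSC events.

    EPSC onsets are aligned to the ripplet troughs of the slice; IPSC onsets
    follow the slice's FS volleys by 0.8 ms (monosynaptic feedforward
    inhibition). ``cell.ei_balance`` trades the relative amplitudes so the
    net charge sign varies across cells (0 = fully excitatory).
    """
    if not (-55.0 <= holding <= -50.0):
        raise ValidationError("holding must lie in [-55, -50] mV")
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    p = p or PopulationParams()
    noise_sd = p.noise_sd_vc if noise_sd is None else noise_sd
    if slice_spec is None:
        slice_spec = SliceSpec(
            volley_times=np.asarray(p.presyn_volley_means, float),
            ripplet_times=np.asarray(p.ripplet_peak_means, float),
            fs_spike_times=np.asarray(p.fs_spike_means, float),
        )
    t = _time_axis(protocol, rate, sweep_ms)
    onset = protocol.onset
    rng = np.random.default_rng([seed, 404])

    epsc_onsets = onset + trough_times_for_slice(slice_spec)
    ipsc_onsets = onset + slice_spec.fs_spike_times + 0.8
    epsc_amp = 65.0 * (1.0 - cell.ei_balance) + 5.0
    ipsc_amp = 45.0 * cell.ei_balance + 5.0

    rows = np.zeros((n_sweeps, t.size))
    for i in range(n_sweeps):
        for te in epsc_onsets:
            a = epsc_amp * rng.uniform(0.85, 1.15)
            rows[i] -= a * _diff_exp(t, te + rng.normal(0, 0.05),
                                     p.epsc_rise_ms, p.epsc_decay_ms)
        for ti in ipsc_onsets:
            a = ipsc_amp * rng.uniform(0.85, 1.15)
            rows[i] += a * _diff_exp(t, ti + rng.normal(0, 0.05),
                                     p.ipsc_rise_ms, p.ipsc_decay_ms)
    rows += np.random.default_rng([seed, 405]).normal(0.0, noise_sd, rows.shape)
    sweeps = [Trace(row, rate=rate, kind="voltage_clamp", holding=holding)
              for row in rows]
    return SweepSet(sweeps=sweeps, protocol=protocol, condition="control",
                    labels={"cell_class": cell.cell_class})


# ---------------------------------------------------------------------------
# Paired spike trains (FS-FS synchrony protocol)
# ---------------------------------------------------------------------------

def synth_pair_trains(
    shared_times,
    sigma_indep: float,
    sigma_common: float,
    n_trials: int,
    seed: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Two cells driven by shared spike volleys.

    Per trial, each shared spike receives a common Gaussian offset
    (``sigma_common``) applied to both cells, and each cell adds an
    independent per-spike offset (``sigma_indep``). The SD of pairwise
    spike-time differences is therefore ``sqrt(2) * sigma_indep``.
    """
    shared_times = np.asarray(shared_times, float)
    if shared_times.size == 0:
        raise ValidationError("shared_times must be nonempty")
    if sigma_indep < 0 or sigma_common < 0:
        raise ValidationError("jitter SDs must be >= 0")
    rng = np.random.default_rng(seed)
    a_trials, b_trials = [], []
    for _ in range(n_trials):
        common = rng.normal(0.0, sigma_common, shared_times.size) if sigma_common \
            else np.zeros(shared_times.size)
        base = shared_times + common
        a = base + (rng.normal(0.0, sigma_indep, base.size) if sigma_indep else 0.0)
        b = base + (rng.normal(0.0, sigma_indep, base.size) if sigma_indep else 0.0)
        a_trials.append(np.sort(a))
        b_trials.append(np.sort(b))
    return a_trials, b_trials


# ---------------------------------------------------------------------------
# Current-step family (intrinsic-property characterization)
# ---------------------------------------------------------------------------

def synth_step_family(
    cell_class: str = "FS",
    seed: int = 0,
    v_rest: float = -70.0,
    r_in_mohm: float = 100.0,
    tau_m_ms: float = 12.0,
    rheobase_pa: float = 120.0,
    i_max_pa: float = 400.0,
    f_max_hz: float = 250.0,
    rate: float = DEFAULT_RATE_HZ,
    noise_sd: float = 0.15,
) -> SweepSet:
    """Synthetic 600 ms current-step family for intrinsic-parameter extraction.

    Spikes are stylized exponential upstrokes (time constant per class), so
    the dV/dt = 5 V/s threshold, half-width, AHP, input resistance, Imax and
    Fmax are all well defined by construction. Steps above ``i_max_pa`` show
    a 20% first-spike height reduction. Entirely synthetic; amplitudes are
    not calibrated to any recorded cell.
    """
    if cell_class == "FS":
        tau_up, tau_down, spike_peak, ahp = 0.20, 0.35, 30.0, 12.0
    else:
        tau_up, tau_down, spike_peak, ahp = 0.45, 0.9, 35.0, 6.0
        f_max_hz = min(f_max_hz, 45.0)
    step_on, step_ms, sweep_ms = 50.0, 600.0, 700.0
    t = np.arange(int(sweep_ms * rate / 1000.0)) / rate * 1000.0
    sub = [-60.0, -40.0, -20.0, 20.0, 40.0, 60.0]
    supra = sorted({rheobase_pa, 200.0, 300.0, i_max_pa, i_max_pa + 100.0})
    currents = sub + supra
    rng = np.random.default_rng(seed)

    rows = []
    for i_pa in currents:
        dv = i_pa * r_in_mohm / 1000.0      # pA * MOhm -> mV
        v = np.full(t.size, v_rest)
        in_step = (t >= step_on) & (t < step_on + step_ms)
        rise = 1.0 - np.exp(-(t[in_step] - step_on) / tau_m_ms)
        v[in_step] += dv * rise
        v[t >= step_on + step_ms] += dv * np.exp(
            -(t[t >= step_on + step_ms] - step_on - step_ms) / tau_m_ms)
        if i_pa >= rheobase_pa:
            height_scale = 0.8 if i_pa > i_max_pa else 1.0
            if i_pa == rheobase_pa:
                spike_times = [step_on + 25.0]
            else:
                frac = (i_pa - rheobase_pa) / (i_max_pa - rheobase_pa)
                steady = f_max_hz * (0.4 + 0.6 * min(frac, 1.2))
                isi = 1000.0 / steady
                first = step_on + 8.0
                spike_times = list(np.arange(first, step_on + step_ms - 2.0, isi))
                if cell_class == "RS" and len(spike_times) > 2:
                    # initial fast doublet, then slow steady firing
                    spike_times = [first, first + 6.0] + [
                        s for s in spike_times[1:] if s > first + 25.0]
            # spike amplitude rides the plateau so first-spike height is
            # constant below i_max and drops 20% above it
            amp = (spike_peak - v_rest) * height_scale
            for ts in spike_times:
                up = (t > ts - 8 * tau_up) & (t <= ts)
                v[up] += amp * np.exp((t[up] - ts) / tau_up)
                down = t > ts
                v[down] += amp * np.exp(-(t[down] - ts) / tau_down)
                v -= ahp * _gaussian(t, ts + 1.2, 1.2)
        v += rng.normal(0.0, noise_sd, v.size)
        rows.append(v)

    proto = StimulusProtocol(onset=step_on, duration=step_ms, intensity=1.0)
    labels = {
        "step_pa": ";".join(f"{c:g}" for c in currents),
        "step_onset_ms": f"{step_on:g}",
        "step_duration_ms": f"{step_ms:g}",
        "cell_class": cell_class,
    }
    sweeps = [Trace(row, rate=rate, kind="current_clamp") for row in rows]
    return SweepSet(sweeps=sweeps, protocol=proto, condition="control",
                    labels=labels)
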