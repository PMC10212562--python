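"""Event-driven simulator of the proposed ripplet-generating L4 circuit.

The model is a timed feedforward cascade, not a conductance model: a single
synchronous thalamocortical (TC) volley excites FS interneurons (first FS
volley 0.8 ms later, a monosynaptic latency) and RS excitatory cells (first
RS spike packet 1.7 ms after the TC volley). Each RS packet drives the next
one after one cycle period -- the sum of the RS->RS synaptic delay (0.9 ms)
and the postsynaptic time-to-spike (1.5 ms) -- and drives an FS volley 1.5 ms
after itself (faster FS kinetics). Each FS volley sends feedforward IPSPs
that arrive in RS cells 0.8 ms later and preempt any RS cell whose threshold
crossing would come after that arrival; this enforces packet synchrony.
Per-cycle synaptic depression shrinks successive packets until one falls
below the minimum size and the cascade terminates -- FS cells fire on every
cycle, so a normally terminated run has exactly one more FS volley than RS
volleys. Disinhibition (gabazine mode) removes the preemption and the
per-cycle depression; a slow adaptation clock then winds the cascade down
over hundreds of ms, reproducing bounded paroxysmal discharges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trace, ValidationError, get_logger
from .synth import _gaussian, _half_cosine

__all__ = ["CircuitParams", "SimResult", "simulate_ripplet", "summarize_sim",
           "sim_lfp"]

log = get_logger(__name__)

_MAX_CYCLES = 2000


@dataclass(frozen=True)
class CircuitParams:
    """Delays, packet statistics and gating flags of the cascade model."""

    n_rs: int = 200
    n_fs: int = 20
    tc_time: float = 0.0            # ms; the TC volley launches everything
    fs_first_latency: float = 0.8   # TC -> first FS volley (monosynaptic)
    rs_first_offset: float = 1.7    # TC -> first RS packet center
    syn_delay_rs: float = 0.9       # RS -> RS synaptic delay
    tts_rs: float = 1.5             # EPSP onset -> RS spike (time to spike)
    rs_to_fs_total: float = 1.5     # RS packet -> FS volley (1.1 delay + 0.4 tts)
    fs_to_ipsp_delay: float = 0.8   # FS volley -> IPSP arrival in RS cells
    sigma_rs: float = 0.3           # SD of RS threshold-crossing times, ms
    fs_jitter_ms: float = 0.05      # FS spike jitter around a volley
    p0: float = 0.9                 # initial RS participation probability
    depression: float = 0.6         # per-cycle participation multiplier
    n_min: int = 10                 # minimum packet size to sustain the cascade
    refractory_cycles: int = 1      # RS cells skip this many cycles after firing
    inhibition_on: bool = True
    adaptation_tau: float = 150.0   # ms; disinhibited-mode wind-down clock
    seed: int = 0

    @property
    def cycle_period(self) -> float:
        """Oscillation period = RS synaptic delay + RS time-to-spike."""
        return self.syn_delay_rs + self.tts_rs

    def __post_init__(self) -> None:
        if min(self.fs_first_latency, self.rs_first_offset, self.syn_delay_rs,
               self.tts_rs, self.rs_to_fs_total, self.fs_to_ipsp_delay) <= 0:
            raise ValidationError("all delays must be > 0")
        if not 0 < self.depression <= 1:
            raise ValidationError("depression multiplier must be in (0, 1]")
        if self.n_rs < 1 or self.n_fs < 1 or self.n_min < 1:
            raise ValidationError("population sizes must be >= 1")
        if self.sigma_rs < 0 or self.fs_jitter_ms < 0:
            raise ValidationError("jitter SDs must be >= 0")
        if not 0 < self.p0 <= 1:
            raise ValidationError("p0 must be in (0, 1]")


@dataclass
class SimResult:
    """Rasters, volley schedules and packet sizes of one simulated ripplet."""

    rs_raster: list[np.ndarray]
    fs_raster: list[np.ndarray]
    rs_volley_times: np.ndarray
    fs_volley_times: np.ndarray
    packet_sizes: np.ndarray
    duration: float                  # last spike time - TC volley time
    params: CircuitParams

    def to_dict(self) -> dict:
        return {
            "rs_volley_times_ms": list(map(float, self.rs_volley_times)),
            "fs_volley_times_ms": list(map(float, self.fs_volley_times)),
            "packet_sizes": list(map(int, self.packet_sizes)),
            "duration_ms": float(self.duration),
            "n_rs_spikes": int(sum(len(r) for r in self.rs_raster)),
            "n_fs_spikes": int(sum(len(r) for r in self.fs_raster)),
        }


def simulate_ripplet(p: CircuitParams) -> SimResult:
    """Run the event-driven cascade once.

    With inhibition on, RS participation in cycle k is
    ``p0 * depression**(k-1)``; participants draw a threshold-crossing time
    ``N(center_k, sigma_rs)`` and are preempted if it falls after the IPSP
    arrival cutoff (previous FS volley + IPSP delay). A cycle occurs iff the
    surviving packet has at least ``n_min`` cells. With inhibition off there
    is no preemption or depression; participation decays as
    ``exp(-elapsed / adaptation_tau)`` instead.
    """
    rs_raster: list[list[float]] = [[] for _ in range(p.n_rs)]
    fs_raster: list[list[float]] = [[] for _ in range(p.n_fs)]
    fs_volleys: list[float] = []
    rs_volleys: list[float] = []
    packet_sizes: list[int] = []
    last_fired = np.full(p.n_rs, -10**9)

    def fire_fs(volley_time: float) -> None:
        idx = len(fs_volleys)
        fs_volleys.append(volley_time)
        rng = np.random.default_rng([p.seed, 1, idx])
        jit = rng.normal(0.0, p.fs_jitter_ms, p.n_fs) if p.fs_jitter_ms else \
            np.zeros(p.n_fs)
        for c in range(p.n_fs):
            fs_raster[c].append(volley_time + jit[c])

    fire_fs(p.tc_time + p.fs_first_latency)

    for k in range(1, _MAX_CYCLES + 1):
        center = p.tc_time + p.rs_first_offset + (k - 1) * p.cycle_period
        eligible = np.flatnonzero(k - last_fired > p.refractory_cycles)
        if p.inhibition_on:
            prob = p.p0 * p.depression ** (k - 1)
        else:
            prob = p.p0 * np.exp(-(center - p.tc_time) / p.adaptation_tau)
        # per-cycle, per-cell substream: the same (seed, cycle, cell) draw is
        # reused regardless of parameters, giving common random numbers for
        # seeded comparisons across parameter settings
        rng = np.random.default_rng([p.seed, 2, k])
        u = rng.random(p.n_rs)
        z = rng.normal(0.0, 1.0, p.n_rs)
        if p.sigma_rs > 0:
            participating = eligible[u[eligible] < prob]
            crossings = center + p.sigma_rs * z[participating]
        else:
            # noise-free mode: expected packet size, deterministic schedule
            participating = eligible[:int(round(eligible.size * prob))]
            crossings = np.full(participating.size, center)
        if p.inhibition_on and p.sigma_rs > 0:
            # preemption: the IPSP wavefront catches cells still short of
            # threshold. In the noise-free limit all cells cross together and
            # the earliest-cohort-escapes picture degenerates, so preemption
            # only applies when crossing times are dispersed.
            cutoff = fs_volleys[-1] + p.fs_to_ipsp_delay
            survived = crossings <= cutoff
            participating = participating[survived]
            crossings = crossings[survived]
        if participating.size < p.n_min:
            break
        rs_volleys.append(center)
        packet_sizes.append(int(participating.size))
        for cell, t_spike in zip(participating, crossings):
            rs_raster[cell].append(float(t_spike))
        last_fired[participating] = k
        fire_fs(center + p.rs_to_fs_total)

    all_spikes = [t for r in rs_raster for t in r] + \
                 [t for r in fs_raster for t in r]
    duration = max(all_spikes) - p.tc_time if all_spikes else 0.0
    return SimResult(
        rs_raster=[np.sort(np.asarray(r)) for r in rs_raster],
        fs_raster=[np.sort(np.asarray(r)) for r in fs_raster],
        rs_volley_times=np.asarray(rs_volleys),
        fs_volley_times=np.asarray(fs_volleys),
        packet_sizes=np.asarray(packet_sizes, int),
        duration=float(duration),
        params=p,
    )


def summarize_sim(r: SimResult) -> dict:
    """Volley counts, FS volley frequency (1/mean inter-volley interval),
    duration, and the spikes-per-RS-cell histogram."""
    out: dict = {
        "n_rs_volleys": int(r.rs_volley_times.size),
        "n_fs_volleys": int(r.fs_volley_times.size),
        "duration_ms": float(r.duration),
        "packet_sizes": list(map(int, r.packet_sizes)),
    }
    if r.fs_volley_times.size >= 2:
        ivi = np.diff(r.fs_volley_times)
        out["fs_frequency_hz"] = 1000.0 / float(np.mean(ivi))
    else:
        out["fs_frequency_hz"] = None
        log.info("fewer than 2 FS volleys; frequency undefined")
    spikes_per_cell = np.array([len(x) for x in r.rs_raster])
    firing = spikes_per_cell[spikes_per_cell > 0]
    hist = np.bincount(spikes_per_cell,
                       minlength=max(3, spikes_per_cell.max() + 1
                                     if spikes_per_cell.size else 3))
    out["rs_spikes_per_cell_hist"] = list(map(int, hist))
    out["frac_firing_rs_1_2_spikes"] = (
        float(np.mean((firing >= 1) & (firing <= 2))) if firing.size else None)
    return out


# offset of the rendered LFP transient after its RS packet center: population
# RS spikes sit just before the negative LFP peak (161 vs 180 degrees), which
# also puts each transient ~1.05 ms behind the preceding FS volley as observed
_TRANSIENT_OFFSET_MS = 0.15
_PRE_TC_MS = 2.3    # light onset precedes the TC volley by the volley latency


def sim_lfp(r: SimResult, rate: float = 20000.0, sweep_ms: float = 40.0,
            transient_sigma_ms: float = 0.3, volley_amp_mv: float = 0.4,
            envelope_mv: float = 0.15) -> tuple[Trace, "object"]:
    """Render a proxy LFP from a simulation: one negative Gaussian per RS
    packet (amplitude proportional to packet size) just after the packet
    center, a presynaptic volley bump at the TC time, and a slow positive
    envelope. Returns (trace, protocol) suitable for the ripplet detector.
    """
    from .core import StimulusProtocol  # local import to avoid cycle at module load

    onset = 1.0                              # ms of pre-stimulus baseline
    tc = onset + _PRE_TC_MS                  # TC volley position in the sweep
    shift = tc - (r.params.tc_time)          # simulator clock -> sweep clock
    t = np.arange(int(sweep_ms * rate / 1000.0)) / rate * 1000.0
    y = np.zeros_like(t)
    y -= volley_amp_mv * _gaussian(t, tc, 0.25)
    if r.packet_sizes.size:
        ref = float(r.packet_sizes.max())
        first = r.rs_volley_times[0] + shift + _TRANSIENT_OFFSET_MS
        span = (r.rs_volley_times[-1] - r.rs_volley_times[0]
                + 2 * r.params.cycle_period)
        y += envelope_mv * _half_cosine(t, first - r.params.cycle_period, span + 4)
        for center, size in zip(r.rs_volley_times, r.packet_sizes):
            mu = center + shift + _TRANSIENT_OFFSET_MS
            # sub-linear packet-size scaling: even small packets produce a
            # clear current sink (population EPSCs saturate the amplitude)
            amp = 1.5 * (0.3 + 0.7 * size / ref)
            y -= amp * _gaussian(t, mu, transient_sigma_ms)
    proto = StimulusProtocol(onset=onset, duration=2.0, intensity=0.9)
    return Trace(y, rate=rate, kind="lfp"), proto
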