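#!/usr/bin/env python
"""Phase locking of FS/RS spikes to ripplets and E-I sequence analysis.

Part 1 assigns phases to FS and RS spike cohorts drawn at the published
phase statistics (FS near troughs, RS near peaks) and converts the median
phase separation to time. Part 2 detects EPSC/IPSC onset alternations in
synthetic voltage-clamp sweeps, computes net charge across the E-I balance
range, and regresses EPSC onsets on ripplet trough times (slope ~1).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rippletlab import core, events, phases, stats, synth

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

pop = synth.PopulationParams()
proto = core.StimulusProtocol(onset=1.0, duration=2.0, intensity=0.9)
rng = np.random.default_rng(SEED)

# --- phase cohorts at the published statistics -----------------------------
fs_angles = rng.normal(pop.fs_phase_deg[0], 25, 28)
rs_angles = rng.normal(pop.rs_phase_deg[0], 12, 13)
fs_sum = phases.phase_summary(fs_angles)
rs_sum = phases.phase_summary(rs_angles)
sep_deg = rs_sum.median_deg - fs_sum.median_deg
sep_ms = phases.phase_to_time(sep_deg, 1000.0 / 408.0)
perm = stats.permutation_test(fs_angles, rs_angles, seed=SEED)
print(f"FS median phase {fs_sum.median_deg:.0f} deg, RS "
      f"{rs_sum.median_deg:.0f} deg; separation {sep_deg:.0f} deg = "
      f"{sep_ms:.1f} ms at 408 Hz ({perm.formatted_p()}, permutation test)")

# --- E-I sequences ---------------------------------------------------------
spec = synth.SliceSpec(
    volley_times=np.asarray(pop.presyn_volley_means, float),
    ripplet_times=np.asarray(pop.ripplet_peak_means, float),
    fs_spike_times=np.asarray(pop.fs_spike_means, float))
rows = []
for i, bal in enumerate(np.linspace(0.2, 0.8, 7)):
    cell = synth.RealizedCell("RS", np.array([4.3, 6.4]),
                              np.array([0.1, 0.25]), np.array([0.9, 0.35]),
                              v_rest=-75.0, ei_balance=float(bal))
    vc = synth.synth_voltage_clamp_sweeps(cell, proto, 20, SEED * 10 + i,
                                          slice_spec=spec)
    avg = core.average_sweeps(vc)
    seq = events.detect_ei_onsets(avg, proto)
    q = events.net_charge(avg, (proto.onset, 30.0), protocol=proto)
    try:
        ei_anchors = phases.anchors_from_ei(seq)
        fs_phase = phases.assign_phase(proto.onset + spec.fs_spike_times,
                                       ei_anchors)
    except core.ValidationError:     # too few events for a phase cycle
        fs_phase = np.array([])
    rows.append({"ei_balance": round(bal, 2),
                 "n_epsc": len(seq.epsc_onsets),
                 "n_ipsc": len(seq.ipsc_onsets),
                 "net_charge_pa_ms": q,
                 "fs_phase_median_deg": (float(np.median(fs_phase))
                                         if fs_phase.size else np.nan)})
df = pd.DataFrame(rows)
df.to_csv(OUT / "ei_sequences.csv", index=False)
print(df.round(2))

# --- trough-EPSC regression (Fig-5E style) ---------------------------------
troughs, onsets = [], []
for i in range(8):
    sl = synth.draw_slices(pop, 1, SEED * 100 + i)[0]
    cell = synth.RealizedCell("RS", np.array([4.3]), np.array([0.1]),
                              np.array([0.9]), ei_balance=0.5)
    vc = synth.synth_voltage_clamp_sweeps(cell, proto, 15, SEED * 200 + i,
                                          slice_spec=sl)
    seq = events.detect_ei_onsets(core.average_sweeps(vc), proto)
    true_troughs = synth.trough_times_for_slice(sl)
    for onset in seq.epsc_onsets - proto.onset:
        trough = true_troughs[np.argmin(np.abs(true_troughs - onset))]
        if abs(trough - onset) < 1.0:
            troughs.append(trough)
            onsets.append(onset)
slope, intercept, r2 = events.trough_epsc_regression(troughs, onsets)
reg = {"slope": slope, "intercept_ms": intercept, "r_squared": r2,
       "n_pairs": len(troughs)}
(OUT / "trough_epsc_regression.json").write_text(json.dumps(reg, indent=2)
                                                 + "\n")
print(f"EPSC onset = {slope:.2f} x trough {intercept:+.2f} ms "
      f"(R^2 = {r2:.3f}, n = {len(troughs)} pairs)")
print(f"wrote {OUT / 'ei_sequences.csv'}")
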