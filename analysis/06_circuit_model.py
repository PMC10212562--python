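#!/usr/bin/env python
"""Event-driven simulation of the proposed ripplet-generating circuit.

Runs the feedforward E-I cascade (1) noise-free, confirming the exact
2.4 ms inter-volley schedule; (2) at stochastic defaults over 100 seeds,
confirming termination under 25 ms with one more FS than RS volley and RS
cells firing 1-2 spikes; (3) disinhibited, reproducing prolonged paroxysmal
discharges; and renders a proxy LFP whose detected transients match the RS
packet count and sit ~half a cycle after the preceding FS volley.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rippletlab import circuit, lfp

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

nf = circuit.simulate_ripplet(circuit.CircuitParams(sigma_rs=0.0,
                                                    fs_jitter_ms=0.0,
                                                    seed=SEED))
print(f"noise-free schedule: RS inter-volley intervals "
      f"{np.unique(np.round(np.diff(nf.rs_volley_times), 6))} ms "
      f"(= synaptic delay 0.9 + time-to-spike 1.5)")

rows = []
for s in range(100):
    r = circuit.simulate_ripplet(circuit.CircuitParams(seed=s))
    sm = circuit.summarize_sim(r)
    rows.append({"seed": s, "n_rs_volleys": sm["n_rs_volleys"],
                 "n_fs_volleys": sm["n_fs_volleys"],
                 "duration_ms": sm["duration_ms"],
                 "fs_freq_hz": sm["fs_frequency_hz"],
                 "frac_rs_1_2": sm["frac_firing_rs_1_2_spikes"]})
df = pd.DataFrame(rows)
df.to_csv(OUT / "circuit_runs.csv", index=False)
print(f"stochastic defaults over 100 seeds: duration max "
      f"{df.duration_ms.max():.1f} ms (< 25), RS volleys "
      f"{int(df.n_rs_volleys.min())}-{int(df.n_rs_volleys.max())}, FS = RS+1 "
      f"on {(df.n_fs_volleys == df.n_rs_volleys + 1).sum()}/100 runs, "
      f"FS volley frequency {df.fs_freq_hz.mean():.0f} Hz")

dis = circuit.simulate_ripplet(circuit.CircuitParams(inhibition_on=False,
                                                     seed=SEED))
print(f"disinhibited (gabazine) mode: discharge lasts {dis.duration:.0f} ms "
      f"(paroxysmal, vs <25 ms with inhibition intact)")

r = circuit.simulate_ripplet(circuit.CircuitParams(seed=SEED))
trace, proto = circuit.sim_lfp(r)
f = lfp.detect_ripplet_features(trace, proto)
fsv = r.fs_volley_times + 2.3
lags = [float(tt - fsv[fsv < tt].max()) for tt in f.transient_times
        if np.any(fsv < tt)]
summary = {
    "noise_free_interval_ms": float(np.diff(nf.rs_volley_times)[0]),
    "max_duration_ms": float(df.duration_ms.max()),
    "disinhibited_duration_ms": float(dis.duration),
    "proxy_lfp_transients": f.n_transients,
    "rs_volleys": int(r.rs_volley_times.size),
    "median_transient_lag_after_fs_ms": float(np.median(lags)),
}
(OUT / "circuit_summary.json").write_text(json.dumps(summary, indent=2)
                                          + "\n")
print(f"proxy LFP: {f.n_transients} transients for "
      f"{r.rs_volley_times.size} RS packets; transients lag the preceding "
      f"FS volley by {np.median(lags):.2f} ms (~0.44 of a cycle)")
print(f"wrote {OUT / 'circuit_runs.csv'}")
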