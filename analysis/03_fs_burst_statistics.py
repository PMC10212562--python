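#!/usr/bin/env python
"""Per-order FS burst statistics across a simulated 25-cell cohort.

Detects spikes on every sweep, assigns spike orders across trials, and
tabulates per-order latency, jitter (SD of peak times), CV and reliability,
plus the per-cell burst frequency (reciprocal of the mean ISI). Cohort
numbers track the published 23-183 us jitters, 0.7-1.8% CVs and ~418 Hz
burst frequency.
"""

from pathlib import Path

import pandas as pd

from rippletlab import core, spikes, synth

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)
SEED, N_CELLS = 1, 25

pop = synth.PopulationParams()
proto = core.StimulusProtocol(onset=1.0, duration=5.0, intensity=0.9)

rows = []
for i, cell in enumerate(synth.draw_cells(pop, N_CELLS, SEED)):
    ss = synth.synth_current_clamp_sweeps(cell, proto, 30, SEED * 100 + i, pop)
    bs = spikes.burst_stats(
        spikes.assign_spike_orders(spikes.detect_spike_trains(ss)))
    for k in range(bs.order_means_ms.size):
        rows.append({
            "cell": i, "order": k + 1,
            "latency_ms": bs.order_means_ms[k] - proto.onset,
            "jitter_us": bs.order_jitters_us[k],
            "cv_pct": bs.order_cvs_pct[k],
            "reliability": bs.order_reliability[k],
            "burst_freq_hz": bs.burst_frequency_hz,
        })

df = pd.DataFrame(rows)
df.to_csv(OUT / "fs_burst_stats.csv", index=False)
per_order = df.groupby("order")[["latency_ms", "jitter_us", "cv_pct",
                                 "reliability"]].mean().round(2)
print(per_order)
freq = df.groupby("cell").burst_freq_hz.first().mean()
print(f"cohort burst frequency {freq:.0f} Hz (published 418 +/- 9.5)")
print(f"wrote {OUT / 'fs_burst_stats.csv'}")
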