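#!/usr/bin/env python
"""Generate the synthetic cohort every later step analyzes.

Writes sweep-table CSVs for one example slice (LFP under control, CNQX+APV
and TTX), one FS cell (current clamp at high and low light intensity), one
RS cell (voltage clamp), and a cohort manifest. All later scripts regenerate
what they need from seeds; these files are for inspection and for the CLI.
"""

import json
from pathlib import Path

import numpy as np

from rippletlab import core, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

pop = synth.PopulationParams()
proto = core.StimulusProtocol(onset=1.0, duration=2.0, intensity=0.9)

spec = synth.draw_slices(pop, 1, SEED)[0]
for condition in ("control", "cnqx_apv", "ttx"):
    ss = synth.synth_lfp_sweeps(spec, proto, condition, 20, SEED, pop)
    core.write_sweepset(ss, OUT / f"lfp_{condition}.csv")
print(f"slice event times (ms from light onset): volleys "
      f"{np.round(spec.volley_times, 2)}, transients "
      f"{np.round(spec.ripplet_times, 2)}")

fs_cell = synth.draw_cells(pop, 1, SEED)[0]
for intensity, tag in ((0.9, "high"), (0.2, "low")):
    p = core.StimulusProtocol(onset=1.0, duration=5.0, intensity=intensity)
    ss = synth.synth_current_clamp_sweeps(fs_cell, p, 20, SEED, pop)
    core.write_sweepset(ss, OUT / f"fs_cc_{tag}_intensity.csv")

rs_cell = synth.RealizedCell("RS", np.array([4.3, 6.4]), np.array([0.1, 0.25]),
                             np.array([0.9, 0.35]), v_rest=-75.0,
                             ei_balance=0.5)
vc = synth.synth_voltage_clamp_sweeps(rs_cell, proto, 20, SEED,
                                      slice_spec=spec)
core.write_sweepset(vc, OUT / "rs_vc.csv")

step_fam = synth.synth_step_family("FS", seed=SEED)
core.write_sweepset(step_fam, OUT / "fs_step_family.csv")

manifest = {
    "seed": SEED,
    "files": sorted(p.name for p in OUT.glob("*.csv")),
    "fs_cell_mean_times_ms": list(np.round(fs_cell.mean_times, 3)),
}
(OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
print(f"wrote {len(manifest['files'])} sweep tables under {OUT}")
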