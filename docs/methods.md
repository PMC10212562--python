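# Methods

`rippletlab` re-implements, end to end, the quantitative workflow of an ex
vivo study of "ripplets": transient (<25 ms), ~400 Hz local-field-potential
(LFP) oscillations evoked in layer 4 of mouse barrel cortex by brief
optogenetic activation of thalamocortical (TC) axons. No raw recordings are
distributed with the study, so the package pairs every analysis with a
synthetic-data generator that reproduces the *published statistical
structure* of the recordings; the analyses are written exactly as they would
be applied to real sweeps, and the generator is the test harness that shows
they recover what was put in.

## The experimental model in brief

A light pulse fires most TC terminals in a barrel near-synchronously. The
LFP response decomposes pharmacologically into a stimulus artifact (isolated
by TTX), a presynaptic TC volley component (isolated by CNQX+APV, i.e.
iGluR blockade), and a postsynaptic component (control minus blocked): 2–5
negative transients riding a slow positive envelope. Fast-spiking (FS)
interneurons fire sub-millisecond-precise 4-spike bursts aligned with the
LFP troughs; regular-spiking (RS) excitatory cells fire 1–2 spikes near the
LFP peaks; voltage-clamped RS cells at −50 to −55 mV show alternating
EPSC/IPSC sequences whose EPSC onsets align with the troughs. The proposed
generator circuit is a feedforward cascade: each RS spike packet drives the
next (cycle = synaptic delay 0.9 ms + time-to-spike 1.5 ms = 2.4 ms) and
drives an FS volley 1.5 ms after itself; each FS volley sends feedforward
IPSPs that preempt laggard RS cells 0.8 ms later, enforcing synchrony.

## Synthetic-data generator

Hierarchy: population → slice/cell → trial.

* **Population.** Event-time means and SEMs as published: presynaptic
  volleys 2.3/6.0/10.8 ms (SEMs 0.07/0.22/0.24, n = 8 slices), ripplet
  transients 4.4/6.5/8.9/11.9 ms (SEMs 0.11/0.26/0.30/0.38, n = 11), FS
  spikes 3.1/5.5/7.7/10.3 ms (SEMs 0.06/0.08/0.12/0.14, n = 25 cells), FS
  trial jitters 23/63/110/183 μs, first three ISIs 2.4/2.2/2.7 ms.
* **Slice/cell draws.** Per-order SD = SEM·√n. The default (`correlated=True`)
  draw decomposes this into a shared slice offset (SD of order 1), a shared
  period-scaling factor (fitted so later orders reach their printed SDs),
  and a small 0.15 ms independent residual. This keeps within-slice event
  spacing realistic — the printed smallest inter-peak interval is 2.1 ms,
  and independent per-order draws with SDs up to 1.3 ms would scramble it.
  Draws whose spacing deviates from the mean gap by more than
  (smallest mean gap − 1.7 ms) are rejected; the bound is symmetric about
  the mean gap, so cohort means stay unbiased (verified by test).
  `correlated=False` gives fully independent per-order draws, which is the
  protocol the cohort-frequency reproductions specify.
* **Trials.** LFP sweeps are strictly additive — artifact square pulse
  (−0.08 mV during the light), negative Gaussian volleys (σ 0.25 ms),
  negative Gaussian transients (σ 0.35 ms) on a half-cosine positive
  envelope (0.35 mV, 12 ms), white noise (0.02 mV SD) — so the TTX and
  CNQX+APV subtractions are exact inverses of the construction before noise.
  Pulses ≥5 ms recruit all three volleys; 1 ms pulses attenuate the last
  transient. Current-clamp sweeps place stylized spikes (Gaussian, class-
  specific width) at per-order times with per-trial Gaussian jitter; jitter
  scales as (0.9/intensity)^0.6 (≈2.5× at 20% intensity, matching the
  printed 106 vs 43 μs contrast) and late-order reliability falls with
  intensity while the first spike stays reliable. Voltage-clamp sweeps sum
  difference-of-exponential kernels: EPSCs (rise 0.2, decay 1.0 ms,
  negative) at the slice's trough times, IPSCs (rise 0.4, decay 2.5 ms,
  positive) 0.8 ms after each FS volley; `ei_balance` trades their
  amplitudes so net charge crosses zero across cells. Events are evaluated
  in continuous time at the sample points, so 23 μs jitters are
  representable at the 50 μs sampling period.
* Amplitudes are free choices (the study reports only the ≥0.5 mV inclusion
  criterion); transient amplitudes default to 0.7–1.5 mV so that every
  transient dips below the absolute detection threshold even on the
  positive envelope.

What the generator does *not* emulate: electrode drift and 1/f noise,
correlations between modalities recorded in different cells, unclamped
spikes in voltage clamp, the rising-phase "hump", and any biophysics —
passing tests show the estimators are correct and well-calibrated on data
with the published structure, not that they are robust to every artifact of
real recordings.

## Analysis choices

* **Ripplet detection.** Zero-phase 1.3 kHz Butterworth low-pass (mirroring
  the acquisition filter), transient candidates = local minima below
  −0.1 mV in a 3–20 ms post-onset window, deepest-first with ≥1.5 ms
  separation, sub-sample localization by 3-point parabolic interpolation
  (needed because the printed jitters are below the sample period). Troughs
  are the maxima between consecutive transients plus the leading trough, so
  trough count = transient count and anchors alternate. Slices whose
  largest transient is under 0.5 mV are flagged excluded, as published.
  Volleys are measured on the CNQX+APV trace when available (explicitly so
  in the source study), in a 1–3.5 ms window by default.
* **Burst statistics.** Spike orders are assigned by matching to a template
  of per-order medians initialized from the modal-spike-count trials and
  re-estimated once; per-order jitter uses only trials where that order
  fired (n−1 SD). CV = SD/mean; burst frequency = 1/mean ISI per cell, and
  cohort summaries average per-cell frequencies (this is why the published
  cohort values 418/408/239 Hz exceed the naive reciprocals of the mean
  ISIs — Jensen's inequality on 1/x).
* **Intrinsic parameters.** Threshold at dV/dt = 5 V/s (interpolated),
  height and half-width between threshold and peak, AHP to the post-spike
  trough, input resistance from the I–V slope within ±15 mV, Imax before a
  >10% first-spike height drop (the study says only "noticeable"), Fmax =
  reciprocal of the mean of the last five ISIs at Imax. FS/RS classification
  is a threshold rule (FS: Fmax ≥ 150 Hz and width ≤ 0.5 ms; RS: Fmax
  < 100 Hz and width > 0.5 ms; else unclassified) standing in for the
  unspecified cluster analysis.
* **JBSI.** Synchrony S = fraction of the sparser train's spikes within SW
  of the denser train; chance ⟨S_J⟩ computed analytically per spike as the
  measure of (∪_b [b−SW, b+SW]) ∩ [a−J, a+J] over 2J with overlapping
  windows merged exactly; JBSI = β(S−⟨S_J⟩) with J = 2·SW, β = 2 (the
  uniform jitter distribution is the reading consistent with the index
  being bounded at 1 under these constants). Trials are pooled by counts,
  never matched across boundaries; equal-count ties jitter the first
  argument; positive lag shifts the jittered train later. A Monte-Carlo
  estimator of ⟨S_J⟩ is kept as an independent oracle and agrees with the
  analytic path to within binomial error. Pairwise precision = smallest SW
  (0.1 ms grid) whose best-lag JBSI exceeds 0.5; pairwise lag = argmax over
  lags in that row.
* **Phases.** Anchors alternate in 180° steps (troughs/EPSC onsets ≡ 0 mod
  360°); spike phases interpolate linearly between bracketing anchors and
  are re-expressed relative to the nearest cycle reference. Statistics are
  medians and 10–90th percentiles on the *linear* scale — the published
  plots run past +180° (to 187°), so circular statistics would be the wrong
  summary. Spikes up to a quarter half-cycle past the final anchor are
  extrapolated (this is how a phase slightly beyond +180° can arise);
  anything further is excluded and counted.
* **E–I onsets.** Event extrema are found by *prominence* (5 baseline MADs)
  because events ride each other's decays; the deflection sign gives the
  class. Onsets are slope *steps*: a synaptic current's derivative jumps at
  its onset, so a matched forward-minus-backward short-window (0.15 ms)
  slope difference spikes at the onset while suppressing the smooth slope
  changes of neighbouring peaks and decays. The search for each onset
  starts 0.5 ms after the previous event's onset (clearing that event's
  post-onset slope rebound), and candidates that are weak (<8% of the
  strongest step) or sit at the window edge are rejected as returns toward
  baseline. Alternation is enforced by dropping the smaller of two
  consecutive same-class events; a leading lone EPSC is legitimate (the
  first IPSC is typically occluded). Slope-threshold backtracking — the
  more obvious operationalization of onsets "marked by eye" — was tried
  first and abandoned: with a 2.4 ms cycle shorter than the 2.5 ms IPSC
  decay it lands inside the preceding event and cannot meet the 0.15 ms
  closure this package holds itself to.
* **Statistics.** Two-tailed Monte-Carlo permutation test (10,000 label
  shuffles, |statistic| exceedance, observed arrangement not counted; zero
  exceedances reported as the bound p < 1/n_perm) and the exact two-sided
  sign test. Type-I error is verified at 5% ± 1.5% by simulation.

## Circuit simulator

Volley-level event-driven dynamics, not membrane equations — the published
model is a timed cascade diagram, and conductance models would add
unconstrained parameters. Defaults: 200 RS / 20 FS cells; first FS volley
0.8 ms after the TC volley (monosynaptic); first RS packet at 1.7 ms
(reconciling the 0.8 ms FS latency with FS leading RS by ~0.9 ms); cycle
2.4 ms; FS volleys 1.5 ms after RS packets; IPSP arrival 0.8 ms after FS
volleys; RS crossing-time SD 0.3 ms; initial participation 0.9 with
per-cycle depression ×0.6; packets under 10 cells end the cascade; RS cells
are refractory for one cycle. With these delays the IPSP cutoff sits 0.1 ms
before the packet center, so ~Φ(−1/3) ≈ 37% of participants escape
preemption — the "earliest cohort fires, laggards are preempted" picture.
Runs terminate in 3–6 volleys, under 25 ms, with exactly one more FS than
RS volley, and ≥90% of firing RS cells fire 1–2 spikes.

In the noise-free mode (sigma_rs = 0) all crossings coincide, so the
escape-cohort picture degenerates; preemption is bypassed and packets take
their expected sizes, making the run a pure schedule check (all
inter-volley intervals exactly 2.4 ms). Randomness is drawn from per-cycle,
per-cell substreams so that seeded comparisons across parameter settings use
common random numbers.

Disinhibited (gabazine) mode removes preemption and per-cycle depression;
participation instead decays as exp(−t/150 ms). The adaptation clock is an
explicit modeling device to give the paroxysmal discharge a finite
(hundreds of ms) duration, as observed; its constant is a calibration, not
a measured quantity.

The proxy LFP renders one negative Gaussian (σ 0.3 ms) per RS packet at the
packet center + 0.15 ms, amplitude sub-linearly scaled with packet size
(1.5·(0.3 + 0.7·relative size) mV — population EPSC sinks saturate, and
this keeps late small packets detectable), plus a volley bump at the TC
time and a small positive envelope. The +0.15 ms offset places each
transient ~1.05 ms behind the preceding FS volley, i.e. ~0.44 of a cycle,
reproducing the published anti-phase geometry (RS spikes just before the
negative peak, FS spikes just after the troughs); rendering the transient a
full synaptic delay after the packet was considered and rejected because it
contradicts that geometry.

## Numerical conventions, degenerate inputs, limitations

All times are ms, double precision, measured from light onset in reported
features; sweeps serialize to a plain-text sweep-table CSV at 6 decimals
that round-trips byte-identically. Empty spike trains make the JBSI NaN
(flagged) rather than raising; matrices propagate NaNs per cell. Orders
present in fewer than two trials have undefined jitter. Flat LFPs are
flagged below the amplitude criterion. The detector grids, thresholds and
windows are all exposed in flat YAML config keys mirroring the defaults
above.

Problem sizes used by the test-suite and the reproduction registry —
cohorts of 100 units for the frequency recoveries, 6 pairs × 30 trials for
synchrony, 100 seeds for the simulator bound, 12–25 cells/slices for
pipeline closures — were chosen to put Monte-Carlo error well inside each
quantity's published uncertainty while keeping any single check in the
seconds range.

Known limitations: E–I onset detection degrades for strongly one-sided
cells (|ei_balance| near 0 or 1), where the minority-class events sink
below the noise and alternation enforcement then prunes majority events —
mirroring the occlusion caveats of the source recordings; the FS/RS rule
leaves a deliberate unclassified gap; phase extrapolation past the final
anchor is capped rather than modeled; and the simulator's participation
parameters (p0, sigma_rs) are jointly under-constrained by the published
fractions, so they are free parameters exposed in config.
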