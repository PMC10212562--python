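"""Synthetic-data generator: hierarchy, determinism, additivity, recovery."""

import numpy as np
import pytest

from rippletlab import core, spikes, synth
from rippletlab.core import StimulusProtocol, ValidationError


class TestDrawSlices:
    def test_deterministic_given_seed(self, pop):
        a = synth.draw_slices(pop, 5, seed=42)
        b = synth.draw_slices(pop, 5, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.ripplet_times, y.ripplet_times)
            assert np.array_equal(x.volley_times, y.volley_times)

    def test_zero_sems_reproduce_population_means(self):
        p = synth.PopulationParams(
            presyn_volley_sems=(0.0, 0.0, 0.0),
            ripplet_peak_sems=(0.0, 0.0, 0.0, 0.0),
            fs_spike_sems=(0.0, 0.0, 0.0, 0.0))
        s = synth.draw_slices(p, 3, seed=0)[0]
        assert np.allclose(s.ripplet_times, p.ripplet_peak_means)
        assert np.allclose(s.volley_times, p.presyn_volley_means)

    def test_law_of_large_numbers_first_peak(self, pop):
        cohort = synth.draw_slices(pop, 10_000, seed=7)
        first = np.array([s.ripplet_times[0] for s in cohort])
        se = pop.slice_sds("ripplet")[0] / np.sqrt(len(cohort))
        assert abs(first.mean() - 4.4) < 3 * se + 1e-3

    def test_nonpositive_count_rejected(self, pop):
        with pytest.raises(ValidationError):
            synth.draw_slices(pop, 0, seed=0)

    def test_times_strictly_increasing(self, pop):
        for s in synth.draw_slices(pop, 50, seed=3):
            assert np.all(np.diff(s.ripplet_times) > 0)
            assert np.all(np.diff(s.fs_spike_times) > 0)


class TestLfpSweeps:
    def test_condition_additivity_before_noise(self, pop, proto, default_slice):
        comp = synth.lfp_component_traces(default_slice, proto, 4, seed=9, p=pop)
        control = synth.synth_lfp_sweeps(default_slice, proto, "control", 4,
                                         seed=9, p=pop, noise_sd=0.0)
        total = comp["artifact"] + comp["presynaptic"] + comp["postsynaptic"]
        got = np.stack([sw.samples for sw in control.sweeps])
        assert np.allclose(got, total)

    def test_subtraction_isolates_postsynaptic(self, pop, proto, default_slice):
        kw = dict(n_sweeps=4, seed=9, p=pop, noise_sd=0.0)
        control = synth.synth_lfp_sweeps(default_slice, proto, "control", **kw)
        blocked = synth.synth_lfp_sweeps(default_slice, proto, "cnqx_apv", **kw)
        ttx = synth.synth_lfp_sweeps(default_slice, proto, "ttx", **kw)
        comp = synth.lfp_component_traces(default_slice, proto, 4, seed=9, p=pop)
        # control - blocked isolates the postsynaptic component exactly
        assert np.allclose(control.sweeps[0].samples - blocked.sweeps[0].samples,
                           comp["postsynaptic"][0])
        # ttx leaves only the artifact
        assert np.allclose(ttx.sweeps[0].samples, comp["artifact"][0])

    def test_largest_transient_exceeds_inclusion_criterion(self, pop, proto,
                                                           default_slice):
        s = synth.synth_lfp_sweeps(default_slice, proto, "control", 10, seed=2)
        avg = core.average_sweeps(s)
        assert avg.samples.min() <= -0.5

    def test_short_pulse_limits_presynaptic_volleys(self, pop, default_slice):
        short = StimulusProtocol(onset=1.0, duration=1.0)
        comp = synth.lfp_component_traces(default_slice, short, 1, seed=1, p=pop)
        t = np.arange(comp["presynaptic"].shape[1]) * 0.05
        late = comp["presynaptic"][0][t > 1.0 + 4.0]
        assert np.min(late) > -0.05   # no 2nd/3rd volley for a 1 ms pulse

    def test_unknown_condition_rejected(self, pop, proto, default_slice):
        with pytest.raises(ValidationError):
            synth.synth_lfp_sweeps(default_slice, proto, "gabazine", 2, seed=0)


class TestCurrentClamp:
    def test_zero_reliability_order_never_fires(self, proto):
        cell = synth.RealizedCell(
            "FS", mean_times=np.array([3.1, 5.5, 7.7]),
            trial_jitters_ms=np.array([0.02, 0.06, 0.1]),
            reliability=np.array([1.0, 0.0, 1.0]))
        s = synth.synth_current_clamp_sweeps(cell, proto, 30, seed=4)
        for sw in s.sweeps:
            times = spikes.detect_spikes(sw)
            # order-2 time (6.5 ms absolute) never appears as a spike
            assert not np.any(np.abs(times - (proto.onset + 5.5)) < 0.5)

    def test_high_intensity_fs_fires_every_order(self, pop, proto):
        cell = synth.RealizedCell(
            "FS", mean_times=np.asarray(pop.fs_spike_means),
            trial_jitters_ms=np.asarray(pop.fs_trial_jitters_us) / 1000.0,
            reliability=np.ones(4))
        s = synth.synth_current_clamp_sweeps(cell, proto, 20, seed=6)
        for sw in s.sweeps:
            assert spikes.detect_spikes(sw).size == 4

    def test_configured_jitter_recovered(self, pop, long_pulse_proto):
        cell = synth.RealizedCell(
            "FS", mean_times=np.asarray(pop.fs_spike_means),
            trial_jitters_ms=np.asarray(pop.fs_trial_jitters_us) / 1000.0,
            reliability=np.ones(4))
        s = synth.synth_current_clamp_sweeps(cell, long_pulse_proto, 100, seed=8)
        st = spikes.assign_spike_orders(spikes.detect_spike_trains(s))
        bs = spikes.burst_stats(st)
        for est, true in zip(bs.order_jitters_us, pop.fs_trial_jitters_us):
            assert est == pytest.approx(true, rel=0.25)

    def test_n_sweeps_validated(self, proto):
        cell = synth.RealizedCell("FS", np.array([3.0]), np.array([0.02]),
                                  np.array([1.0]))
        with pytest.raises(ValidationError):
            synth.synth_current_clamp_sweeps(cell, proto, 0, seed=0)


class TestVoltageClamp:
    def test_fully_excitatory_cell_has_negative_net_charge(
            self, proto, default_slice):
        from rippletlab import events
        cell = synth.RealizedCell("RS", np.array([4.3]), np.array([0.1]),
                                  np.array([1.0]), ei_balance=0.0)
        s = synth.synth_voltage_clamp_sweeps(cell, proto, 10, seed=3,
                                             slice_spec=default_slice)
        avg = core.average_sweeps(s)
        q = events.net_charge(avg, (proto.onset, 30.0), protocol=proto)
        assert q < 0

    def test_onset_order_alternates_by_construction(self, default_slice):
        epsc = synth.trough_times_for_slice(default_slice)
        ipsc = default_slice.fs_spike_times + 0.8
        merged = sorted([(t, "E") for t in epsc] + [(t, "I") for t in ipsc])
        classes = [c for _, c in merged]
        assert all(a != b for a, b in zip(classes, classes[1:]))

    def test_holding_out_of_range_rejected(self, proto, default_slice):
        cell = synth.RealizedCell("RS", np.array([4.3]), np.array([0.1]),
                                  np.array([1.0]))
        with pytest.raises(ValidationError):
            synth.synth_voltage_clamp_sweeps(cell, proto, 2, seed=0,
                                             slice_spec=default_slice,
                                             holding=-40.0)


class TestPairTrains:
    def test_zero_independent_jitter_gives_identical_trains(self):
        a, b = synth.synth_pair_trains([3.1, 5.5], 0.0, 0.1, 20, seed=5)
        for x, y in zip(a, b):
            assert np.allclose(x, y)

    def test_pairwise_difference_sd_is_sqrt2_sigma(self):
        a, b = synth.synth_pair_trains([3.1, 5.5, 7.7, 10.3], 0.15, 0.0,
                                       1000, seed=6)
        diffs = np.concatenate([x - y for x, y in zip(a, b)])
        assert np.std(diffs) == pytest.approx(0.15 * np.sqrt(2), rel=0.05)

    def test_different_seeds_differ(self):
        a1, _ = synth.synth_pair_trains([3.0], 0.1, 0.1, 5, seed=1)
        a2, _ = synth.synth_pair_trains([3.0], 0.1, 0.1, 5, seed=2)
        assert not np.allclose(np.concatenate(a1), np.concatenate(a2))

    def test_empty_shared_times_rejected(self):
        with pytest.raises(ValidationError):
            synth.synth_pair_trains([], 0.1, 0.1, 5, seed=0)
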