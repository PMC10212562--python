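"""Spike detection, order assignment, burst stats, ephys params, classing."""

import numpy as np
import pytest

from rippletlab import spikes, synth
from rippletlab.core import StimulusProtocol, SweepSet, Trace, ValidationError
from rippletlab.spikes import (BurstStats, EphysParams, SpikeTrainSet,
                               assign_spike_orders, burst_stats, classify_cell,
                               coupling_coefficient, detect_spikes)


def _cc_trace(samples):
    return Trace(np.asarray(samples, float), kind="current_clamp")


def _spiky_trace(times_ms, n_ms=30.0, rate=20000.0, amp=80.0, v0=-70.0):
    t = np.arange(int(n_ms * rate / 1000)) / rate * 1000.0
    v = np.full(t.size, v0)
    for mu in times_ms:
        v += amp * np.exp(-0.5 * ((t - mu) / 0.15) ** 2)
    return Trace(v, rate=rate, kind="current_clamp")


class TestDetectSpikes:
    def test_flat_trace_yields_nothing(self):
        assert detect_spikes(_cc_trace(np.full(1000, -70.0))).size == 0

    def test_sub_sample_peak_recovery(self):
        tr = _spiky_trace([5.1234, 9.8765])
        times = detect_spikes(tr)
        assert np.allclose(times, [5.1234, 9.8765], atol=0.01)

    def test_refractory_merge_keeps_larger(self):
        t = np.arange(2000) / 20.0
        v = np.full(t.size, -70.0)
        v += 60 * np.exp(-0.5 * ((t - 10.0) / 0.15) ** 2)
        v += 80 * np.exp(-0.5 * ((t - 10.5) / 0.15) ** 2)
        times = detect_spikes(Trace(v, kind="current_clamp"))
        assert times.size == 1
        assert abs(times[0] - 10.5) < 0.1

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValidationError):
            detect_spikes(Trace(np.zeros(100), kind="lfp"))


class TestOrderAssignment:
    def test_identical_bursts_get_full_orders(self):
        trains = [np.array([3.1, 5.5, 7.7, 10.3])] * 6
        out = assign_spike_orders(SpikeTrainSet(trains))
        for o in out.orders:
            assert list(o) == [1, 2, 3, 4]

    def test_missing_spike_lowers_reliability(self):
        trains = [np.array([3.1, 5.5, 7.7, 10.3])] * 10
        trains.append(np.array([3.1, 5.5, 10.3]))   # spike 3 failed
        out = assign_spike_orders(SpikeTrainSet(trains))
        assert list(out.orders[-1]) == [1, 2, 4]
        bs = burst_stats(out)
        assert bs.order_reliability[2] == pytest.approx(10 / 11)

    def test_stray_spike_left_unassigned(self):
        trains = [np.array([3.1, 5.5, 7.7])] * 4
        trains.append(np.array([3.1, 5.5, 7.7, 15.0]))
        out = assign_spike_orders(SpikeTrainSet(trains))
        assert out.orders[-1][-1] == -1

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValidationError):
            assign_spike_orders(SpikeTrainSet([np.array([1.0])] * 2))


class TestBurstStats:
    def test_cv_identity_and_printed_example(self):
        # 3.1 ms latency with 23 us jitter -> CV 0.7% at one decimal
        rng = np.random.default_rng(0)
        trains = [np.sort(np.array([3.1, 5.5, 7.7, 10.3])
                          + rng.normal(0, [0.023, 0.063, 0.110, 0.183]))
                  for _ in range(400)]
        bs = burst_stats(assign_spike_orders(SpikeTrainSet(trains)))
        assert round(bs.order_cvs_pct[0], 1) == 0.7
        for cv, jit, mean in zip(bs.order_cvs_pct, bs.order_jitters_us,
                                 bs.order_means_ms):
            assert cv * mean == pytest.approx(100 * jit / 1000.0, rel=1e-9)

    def test_burst_frequency_from_printed_isis(self):
        # ISIs 2.4/2.2/2.7 ms -> 1000/2.4333 = 410.96 Hz
        assert spikes.burst_frequency_from_isis([2.4, 2.2, 2.7]) == \
            pytest.approx(410.96, abs=0.01)
        trains = [np.array([3.0, 5.4, 7.6, 10.3])] * 5
        bs = burst_stats(assign_spike_orders(SpikeTrainSet(trains)))
        assert bs.burst_frequency_hz == pytest.approx(410.96, abs=0.01)

    def test_identical_trials_have_zero_jitter(self):
        trains = [np.array([2.0, 4.0])] * 5
        bs = burst_stats(assign_spike_orders(SpikeTrainSet(trains)))
        assert np.allclose(bs.order_jitters_us, 0.0)


class TestEphysParams:
    def test_linear_subthreshold_response_recovers_r_in(self):
        fam = synth.synth_step_family("FS", seed=1, r_in_mohm=100.0)
        p = spikes.extract_ephys_params(fam)
        assert p.r_in == pytest.approx(100.0, abs=2.0)

    def test_f_max_is_reciprocal_of_last_five_isis(self):
        fam = synth.synth_step_family("FS", seed=1, f_max_hz=250.0)
        p = spikes.extract_ephys_params(fam)
        assert p.f_max == pytest.approx(250.0, rel=0.02)
        assert p.i_max == pytest.approx(400.0)

    def test_slow_depolarization_has_no_threshold(self):
        # a ramp at 1 mV/ms never reaches the 5 V/s criterion
        t = np.arange(20000) / 20.0
        v = -70.0 + np.clip(t - 100, 0, None) * 0.001
        with pytest.raises(ValidationError):
            spikes._threshold_crossing(v, v.size - 1, 20000.0)

    def test_v_rest_and_threshold_consistent(self):
        fam = synth.synth_step_family("FS", seed=3, v_rest=-68.0)
        p = spikes.extract_ephys_params(fam)
        assert p.v_rest == pytest.approx(-68.0, abs=0.3)
        assert p.v_threshold > p.v_rest
        assert p.spike_height > 0 and p.swhh > 0


class TestClassification:
    @pytest.mark.parametrize("f_max,swhh,expected", [
        (200.0, 0.3, "FS"),
        (40.0, 0.9, "RS"),
        (120.0, 0.4, "unclassified"),
    ])
    def test_threshold_rule(self, f_max, swhh, expected):
        p = EphysParams(v_rest=-70, v_threshold=-45, spike_height=80,
                        swhh=swhh, ahp=10, r_in=100, i_max=400, f_max=f_max)
        assert classify_cell(p) == expected

    def test_generator_archetypes_separate_cleanly(self):
        for seed in range(4):
            fs = spikes.extract_ephys_params(synth.synth_step_family("FS", seed))
            rs = spikes.extract_ephys_params(synth.synth_step_family("RS", seed))
            assert classify_cell(fs) == "FS"
            assert classify_cell(rs) == "RS"


class TestCouplingCoefficient:
    def _step(self, dv, n=4000, rate=20000.0):
        t = np.arange(n) / rate * 1000.0
        v = np.full(n, -70.0)
        v[(t >= 50) & (t < 150)] += dv
        return Trace(v, rate=rate, kind="current_clamp")

    def test_printed_example(self):
        cc = coupling_coefficient(self._step(-10.0), self._step(-0.08),
                                  step_window=(50.0, 150.0))
        assert cc == pytest.approx(0.8, abs=0.01)

    def test_zero_follower_deflection(self):
        cc = coupling_coefficient(self._step(-10.0), self._step(0.0),
                                  step_window=(50.0, 150.0))
        assert cc == pytest.approx(0.0, abs=1e-9)

    def test_small_driver_deflection_guarded(self):
        with pytest.raises(ValidationError):
            coupling_coefficient(self._step(-0.5), self._step(-0.01),
                                 step_window=(50.0, 150.0))
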