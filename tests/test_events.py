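"""E-I onset detection, net charge, and the trough-EPSC regression."""

import numpy as np
import pytest

from rippletlab import core, events, lfp, synth
from rippletlab.core import StimulusProtocol, Trace, ValidationError
from rippletlab.events import (EISequence, detect_ei_onsets, net_charge,
                               trough_epsc_regression)


def _vc_set(default_slice, proto, ei_balance=0.5, seed=21, n=20):
    cell = synth.RealizedCell("RS", np.array([4.3, 6.4]),
                              np.array([0.1, 0.25]), np.array([0.9, 0.35]),
                              v_rest=-75.0, ei_balance=ei_balance)
    return synth.synth_voltage_clamp_sweeps(cell, proto, n, seed,
                                            slice_spec=default_slice)


class TestDetection:
    def test_generator_closure_within_150us(self, proto, default_slice):
        s = _vc_set(default_slice, proto)
        seq = detect_ei_onsets(core.average_sweeps(s), proto)
        true_e = proto.onset + synth.trough_times_for_slice(default_slice)
        true_i = proto.onset + default_slice.fs_spike_times + 0.8
        assert len(seq.epsc_onsets) == 4 and len(seq.ipsc_onsets) == 4
        assert np.max(np.abs(seq.epsc_onsets - true_e)) < 0.15
        assert np.max(np.abs(seq.ipsc_onsets - true_i)) < 0.15

    def test_alternation_invariant_on_output(self, proto, default_slice):
        for bal in (0.4, 0.5, 0.7):
            s = _vc_set(default_slice, proto, ei_balance=bal, seed=33)
            seq = detect_ei_onsets(core.average_sweeps(s), proto)
            classes = [c for _, c in seq.merged()]
            assert all(a != b for a, b in zip(classes, classes[1:]))

    def test_flat_trace_yields_empty_sequence(self, proto):
        tr = Trace(np.zeros(1000), kind="voltage_clamp", holding=-52.0)
        seq = detect_ei_onsets(tr, proto)
        assert seq.epsc_onsets.size == 0 and seq.ipsc_onsets.size == 0

    def test_two_consecutive_epscs_drop_the_smaller(self, proto):
        t = np.arange(1200) / 20.0
        y = np.zeros(t.size)
        from rippletlab.synth import _diff_exp
        y -= 60 * _diff_exp(t, 5.0, 0.2, 1.0)
        y -= 25 * _diff_exp(t, 7.0, 0.2, 1.0)     # second E, no I between
        y += 40 * _diff_exp(t, 9.0, 0.4, 2.5)
        tr = Trace(y, kind="voltage_clamp", holding=-52.0)
        seq = detect_ei_onsets(tr, proto)
        assert len(seq.epsc_onsets) == 1
        assert abs(seq.epsc_onsets[0] - 5.0) < 0.2

    def test_holding_out_of_range_rejected(self, proto):
        tr = Trace(np.zeros(100), kind="voltage_clamp", holding=-30.0)
        with pytest.raises(ValidationError):
            detect_ei_onsets(tr, proto)

    def test_nonalternating_sequence_rejected_by_container(self):
        with pytest.raises(ValidationError):
            EISequence(epsc_onsets=np.array([1.0, 2.0]),
                       ipsc_onsets=np.array([5.0]),
                       epsc_amplitudes=np.array([10.0, 10.0]),
                       ipsc_amplitudes=np.array([10.0]))


class TestNetCharge:
    def test_pure_epsc_is_negative(self, proto):
        t = np.arange(1000) / 20.0
        from rippletlab.synth import _diff_exp
        y = -50 * _diff_exp(t, 5.0, 0.2, 1.0)
        tr = Trace(y, kind="voltage_clamp", holding=-52.0)
        assert net_charge(tr, (2.0, 40.0), protocol=proto) < 0

    def test_balanced_areas_cancel(self, proto):
        t = np.arange(2000) / 20.0
        from rippletlab.synth import _diff_exp
        e = 50 * _diff_exp(t, 5.0, 0.2, 1.0)
        area_e = np.trapezoid(e, t)
        i = 50 * _diff_exp(t, 40.0, 0.2, 1.0)
        y = -e + i
        tr = Trace(y, kind="voltage_clamp", holding=-52.0)
        q = net_charge(tr, (2.0, 90.0), protocol=proto)
        assert abs(q) < 0.01 * area_e

    def test_monotone_crossing_in_ei_balance(self, proto, default_slice):
        charges = []
        for bal in np.linspace(0.0, 1.0, 6):
            s = _vc_set(default_slice, proto, ei_balance=float(bal), seed=7)
            avg = core.average_sweeps(s)
            charges.append(net_charge(avg, (proto.onset, 30.0), protocol=proto))
        assert charges[0] < 0 < charges[-1]
        assert np.all(np.diff(charges) > 0)

    def test_empty_window_rejected(self, proto):
        tr = Trace(np.zeros(100), kind="voltage_clamp", holding=-52.0)
        with pytest.raises(ValidationError):
            net_charge(tr, (50.0, 60.0), protocol=proto)


class TestTroughEpscRegression:
    def test_identity_and_shift(self):
        assert trough_epsc_regression([1, 2, 3], [1, 2, 3]) == \
            pytest.approx((1.0, 0.0, 1.0))
        slope, intercept, r2 = trough_epsc_regression(
            [1, 2, 3, 4], [1.2, 2.2, 3.2, 4.2])
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.2, 1.0))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            trough_epsc_regression([1.0], [1.0])
        with pytest.raises(ValidationError):
            trough_epsc_regression([2.0, 2.0], [1.0, 3.0])

    def test_cohort_alignment_of_troughs_and_epsc_onsets(self, pop, proto):
        """Detected EPSC onsets track the same slice's LFP troughs (slope ~1)."""
        troughs_all, onsets_all = [], []
        for seed in range(8):
            spec = synth.draw_slices(pop, 1, 400 + seed)[0]
            lf = synth.synth_lfp_sweeps(spec, proto, "control", 15,
                                        500 + seed, pop)
            f = lfp.detect_ripplet_features(core.average_sweeps(lf), proto)
            cell = synth.RealizedCell("RS", np.array([4.3]), np.array([0.1]),
                                      np.array([0.9]), ei_balance=0.5)
            vc = synth.synth_voltage_clamp_sweeps(cell, proto, 15, 600 + seed,
                                                  slice_spec=spec)
            seq = detect_ei_onsets(core.average_sweeps(vc), proto)
            for onset in seq.epsc_onsets - proto.onset:
                if f.trough_times.size == 0:
                    continue
                trough = f.trough_times[np.argmin(np.abs(f.trough_times - onset))]
                if abs(trough - onset) < 1.0:   # pair corresponding events
                    troughs_all.append(trough)
                    onsets_all.append(onset)
        slope, _, r2 = trough_epsc_regression(troughs_all, onsets_all)
        assert 0.9 <= slope <= 1.1
        assert r2 > 0.95
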