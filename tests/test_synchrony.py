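"""JBSI: closed forms, interval-union chance, MC oracle, matrix summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rippletlab import synth
from rippletlab.synchrony import (JBSIMatrix, JBSIParams, chance_synchrony_mc,
                                  jbsi, jbsi_matrix, precision_and_lag)


class TestClosedForms:
    def test_identical_isolated_trains_score_exactly_one(self):
        # gaps far exceed 2(J+SW): S = 1 and every p_i = SW/J = 1/2
        trains = [[5.0, 20.0, 40.0]]
        for sw in (0.1, 0.3, 1.0):
            v = jbsi(trains, trains, JBSIParams(sw=sw))
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_hand_interval_geometry(self):
        # A={10.0}, B={10.4}, SW=0.3, J=0.6: S=0, p = 0.5/1.2
        v = jbsi([[10.0]], [[10.4]], JBSIParams(sw=0.3))
        assert v == pytest.approx(2 * (0.0 - 0.5 / 1.2), abs=1e-12)

    def test_distant_trains_score_zero(self):
        v = jbsi([[1.0, 2.0]], [[50.0, 60.0]], JBSIParams(sw=0.3))
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_empty_train_flagged_undefined(self):
        assert math.isnan(jbsi([[]], [[1.0]], JBSIParams(sw=0.3)))

    def test_overlapping_windows_not_double_counted(self):
        # two B spikes 0.2 apart share most of their SW windows; the union
        # measure must cap each p_i at 1
        v = jbsi([[10.0]], [[10.0, 10.2]], JBSIParams(sw=0.5))
        # union [9.5, 10.7] within jitter range [9, 11]: p = 1.2/2 = 0.6
        assert v == pytest.approx(2 * (1.0 - 0.6), abs=1e-12)


class TestUpperBoundProperty:
    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=1.0))
    def test_jbsi_never_exceeds_one_with_default_j(self, seed, sw):
        rng = np.random.default_rng(seed)
        a = [np.sort(rng.uniform(0, 30, rng.integers(1, 10)))
             for _ in range(2)]
        b = [np.sort(rng.uniform(0, 30, rng.integers(1, 10)))
             for _ in range(2)]
        v = jbsi(a, b, JBSIParams(sw=float(sw)))
        assert v <= 1.0 + 1e-9


class TestMonteCarloOracle:
    def test_analytic_chance_matches_mc(self):
        from rippletlab.synchrony import _as_trials, _counts_one_trial, \
            _pick_jittered
        rng = np.random.default_rng(3)
        for i in range(8):
            a = [np.sort(rng.uniform(0, 40, 6)) for _ in range(3)]
            b = [np.sort(rng.uniform(0, 40, 8)) for _ in range(3)]
            p = JBSIParams(sw=0.5)
            jit, ref, n_jit = _pick_jittered(_as_trials(a), _as_trials(b))
            analytic = sum(_counts_one_trial(x, y, p.sw, p.j)[1]
                           for x, y in zip(jit, ref)) / n_jit
            n_reps = 3000
            mc = chance_synchrony_mc(a, b, p, n_reps, seed=i)
            se = math.sqrt(max(analytic * (1 - analytic), 1e-4)
                           / (n_reps * n_jit))
            assert abs(analytic - mc) < 4 * se

    def test_isolated_coincident_spikes_have_half_chance(self):
        mc = chance_synchrony_mc([[10.0]], [[10.0]], JBSIParams(sw=0.4),
                                 5000, seed=1)
        assert mc == pytest.approx(0.5, abs=0.03)


class TestRateInvariance:
    def test_appending_distant_synchronous_block_preserves_jbsi(self):
        rng = np.random.default_rng(5)
        base = np.sort(rng.uniform(0, 20, 5))
        a = [base + rng.normal(0, 0.1, 5)]
        b = [base + rng.normal(0, 0.1, 5)]
        v1 = jbsi(a, b, JBSIParams(sw=0.3))
        block = np.arange(200.0, 220.0, 5.0)
        a2 = [np.concatenate([a[0], block])]
        b2 = [np.concatenate([b[0], block])]
        v2 = jbsi(a2, b2, JBSIParams(sw=0.3))
        # the added block is perfectly synchronous and isolated, so it pulls
        # the pooled index toward 1 by exactly its spike share
        n_old, n_new = 5, 4
        expected = (v1 * n_old + 1.0 * n_new) / (n_old + n_new)
        assert v2 == pytest.approx(expected, abs=1e-9)

    def test_independent_poisson_trains_have_near_zero_expectation(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(200):
            a = [np.sort(rng.uniform(0, 100, 20))]
            b = [np.sort(rng.uniform(0, 100, 25))]
            vals.append(jbsi(a, b, JBSIParams(sw=0.5)))
        assert abs(np.mean(vals)) < 0.05


class TestMatrixAndPrecision:
    def test_identical_trains_full_lag_zero_column(self):
        trains = [[5.0, 20.0, 35.0]]
        m = jbsi_matrix(trains, trains)
        col = m.values[:, list(m.lag_grid).index(0.0)]
        assert np.allclose(col, 1.0, atol=1e-9)
        assert m.precision == pytest.approx(0.1)
        assert m.lag_at_precision == pytest.approx(0.0)

    def test_true_lag_recovered_at_argmax(self):
        rng = np.random.default_rng(9)
        base = [np.sort(rng.uniform(0, 30, 6)) for _ in range(5)]
        a = [x for x in base]
        b = [x + 0.3 for x in base]    # B fires 0.3 ms after A
        m = jbsi_matrix(a, b)
        assert abs(m.lag_at_precision) == pytest.approx(0.3, abs=1e-9)

    def test_precision_definition_on_constructed_matrix(self):
        sw_grid = np.array([0.1, 0.2, 0.3, 0.4])
        lag_grid = np.array([0.0])
        values = np.array([[0.2], [0.4], [0.7], [0.8]])
        m = JBSIMatrix(sw_grid, lag_grid, values)
        prec, lag = precision_and_lag(m)
        assert prec == pytest.approx(0.3)

    def test_all_subthreshold_matrix_has_undefined_precision(self):
        m = JBSIMatrix(np.array([0.1, 0.2]), np.array([0.0]),
                       np.array([[0.1], [0.2]]))
        assert precision_and_lag(m) == (None, None)

    def test_pair_protocol_rise_then_collapse(self, pop):
        a, b = synth.synth_pair_trains(pop.fs_spike_means, 0.15, 0.05, 30,
                                       seed=12)
        m = jbsi_matrix(a, b)
        best = np.nanmax(m.values, axis=1)
        by_sw = dict(zip(np.round(m.sw_grid, 1), best))
        assert by_sw[0.3] > 0.5 > by_sw[0.2]
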