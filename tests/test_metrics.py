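"""Selectivity metric, performance bins, group matrices, correlograms,
and the sigmoid fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairnet.metrics import (classify_change, cross_correlogram,
                             group_weight_matrix, network_selectivity,
                             performance_bins, preferred_pairs, selectivity,
                             sigmoid_curve, sigmoid_fit)


class TestSelectivity:
    @pytest.mark.parametrize("rates, expected", [
        ((10, 10, 10, 10), 0.0),   # uniform responder: least selective
        ((12, 0, 0, 0), 3.0),      # single-pair responder: most selective
        ((8, 8, 0, 0), 1.0),       # linear single-stimulus cell
        ((0, 0, 0, 0), 0.0),       # silent cell contributes zero
    ])
    def test_reference_values(self, rates, expected):
        assert selectivity(rates) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    def test_linear_two_stimulus_cell_is_one(self, ra, rb):
        # responds r_A+r_B to the pair, r_A and r_B to the overlaps
        assert selectivity((ra + rb, ra, rb, 0.0)) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1e3), min_size=4, max_size=4))
    def test_bounds(self, rates):
        assert 0.0 <= selectivity(rates) <= 3.0 + 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 100), min_size=4, max_size=4),
           st.floats(0.01, 50))
    def test_scale_invariance(self, rates, c):
        r = np.asarray(rates)
        assert selectivity(c * r) == pytest.approx(selectivity(r), rel=1e-9)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            selectivity((1, -1, 0, 0))


class TestNetworkSelectivity:
    def test_all_uniform_cells(self):
        res = network_selectivity(np.full((10, 4), 10.0))
        assert res.mean == 0.0

    def test_half_selective_half_silent(self):
        rates = np.zeros((10, 4))
        rates[:5, 0] = 12.0
        assert network_selectivity(rates, "all").mean == pytest.approx(1.5)
        assert network_selectivity(rates, "active_only").mean == pytest.approx(3.0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0, 20, (50, 4))
        base = network_selectivity(rates).per_cell
        for _ in range(3):
            perm = np.array([rng.permutation(4) for _ in range(50)])
            shuffled = np.take_along_axis(rates, perm, axis=1)
            np.testing.assert_allclose(network_selectivity(shuffled).per_cell, base)

    def test_active_floor(self):
        rates = np.zeros((2, 4))
        rates[0] = (0.1, 0.1, 0.1, 0.1)  # below the 0.5 Hz floor
        rates[1] = (12, 0, 0, 0)
        res = network_selectivity(rates, "active_only")
        assert res.included.tolist() == [False, True]
        assert res.mean == pytest.approx(3.0)


class TestPerformance:
    def test_reliable_boundary(self):
        flags = [True] * 34 + [False] * 6  # 85%
        assert performance_bins(flags).classification == "reliable"

    def test_unreliable_boundary(self):
        flags = [True] * 30 + [False] * 10  # 75%
        assert performance_bins(flags).classification == "unreliable"

    def test_borderline_band(self):
        flags = [True] * 32 + [False] * 8  # 80%
        assert performance_bins(flags).classification == "borderline"

    def test_all_correct(self):
        trace = performance_bins([True] * 80)
        assert trace.final == 1.0 and trace.classification == "reliable"
        np.testing.assert_allclose(trace.bin_fractions, 1.0)

    def test_bin_count_conservation(self):
        rng = np.random.default_rng(1)
        flags = rng.random(200) < 0.7
        trace = performance_bins(flags)
        assert trace.bin_fractions.size == 5
        assert np.sum(trace.bin_fractions * 40) == pytest.approx(flags[:200].sum())

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            performance_bins([True] * 39)


class TestClassifyChange:
    @pytest.mark.parametrize("initial, final, expected", [
        (1.00, 1.10, "improved"),
        (1.00, 1.04, "unchanged"),
        (1.00, 0.96, "unchanged"),
        (1.00, 0.90, "worsened"),
        (0.00, 0.50, "improved"),
    ])
    def test_five_percent_rule(self, initial, final, expected):
        assert classify_change(initial, final) == expected


class TestGroupWeightMatrix:
    def test_no_change_gives_zero_matrix(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 1, (20, 30))
        pref_pre = rng.integers(0, 4, 20)
        pref_post = rng.integers(0, 4, 30)
        gm = group_weight_matrix(w, w, pref_pre, pref_post)
        np.testing.assert_allclose(np.nan_to_num(gm.matrix), 0.0)

    def test_single_entry_construction(self):
        w0 = np.full((8, 8), 0.5)
        w1 = w0.copy()
        pref_pre = np.repeat([0, 1, 2, 3], 2)
        pref_post = np.repeat([0, 1, 2, 3], 2)
        rows = np.flatnonzero(pref_pre == 0)
        cols = np.flatnonzero(pref_post == 1)
        w1[np.ix_(rows, cols)] = 0.6
        gm = group_weight_matrix(w0, w1, pref_pre, pref_post)
        assert gm.matrix[0, 1] == pytest.approx(0.1)
        others = np.ones((4, 4), dtype=bool)
        others[0, 1] = False
        np.testing.assert_allclose(gm.matrix[others], 0.0)

    def test_empty_group_marked_nan(self):
        w = np.full((4, 4), 0.5)
        pref = np.zeros(4, dtype=int)  # everything prefers pair 0
        gm = group_weight_matrix(w, w, pref, pref)
        assert np.isfinite(gm.matrix[0, 0])
        assert np.isnan(gm.matrix[1:, :]).all()

    def test_inactive_cells_excluded_by_floor(self):
        rates = np.zeros((3, 4))
        rates[0] = (5, 1, 0, 0)
        pref = preferred_pairs(rates, active_floor=0.5)
        assert pref.tolist() == [0, -1, -1]

    def test_diagonal_subtraction(self):
        m = np.arange(16, dtype=float).reshape(4, 4)
        pref = np.repeat([0, 1, 2, 3], 2)
        w1 = np.zeros((8, 8))
        for g in range(4):
            for h in range(4):
                w1[np.ix_(pref == g, pref == h)] = m[g, h]
        gm = group_weight_matrix(np.zeros((8, 8)), w1, pref, pref,
                                 mask=np.ones((8, 8), dtype=bool))
        np.testing.assert_allclose(gm.diagonal_subtracted,
                                   m - np.diag(m)[:, None])


class TestCorrelogram:
    def test_identical_trains_peak_at_zero(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 1000, 50))
        res = cross_correlogram(t, t)
        assert res.lags[np.argmax(res.counts)] == pytest.approx(1.0)  # 0-lag bin

    def test_shifted_train_peak_at_shift(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 1000, 80))
        res = cross_correlogram(t, t + 5.0)
        assert abs(res.lags[np.argmax(res.counts)] - 5.0) <= res.bin_width

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.uniform(0, 500, 40))
        b = np.sort(rng.uniform(0, 500, 60))
        res = cross_correlogram(a, b, max_lag=50.0)
        n_pairs = np.sum(np.abs(b[None, :] - a[:, None]) <= 50.0)
        assert res.counts.sum() == n_pairs

    def test_empty_train(self):
        res = cross_correlogram([], [1.0, 2.0])
        assert res.counts.sum() == 0

    def test_independent_poisson_flat(self):
        rng = np.random.default_rng(3)
        a = np.sort(rng.uniform(0, 100_000, 2000))
        b = np.sort(rng.uniform(0, 100_000, 2000))
        res = cross_correlogram(a, b, max_lag=50.0, bin_width=10.0)
        expected = res.counts.mean()
        assert np.abs(res.counts - expected).max() < 5 * np.sqrt(expected)


class TestSigmoidFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 2, 30)
        y = sigmoid_curve(x, 1.0, 0.2)
        fit = sigmoid_fit(x, y)
        assert fit.x0 == pytest.approx(1.0, abs=1e-4)
        assert fit.delta == pytest.approx(0.2, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_value_is_75(self):
        assert sigmoid_curve(1.0, 1.0, 0.2) == pytest.approx(75.0)

    def test_asymptotes(self):
        assert sigmoid_curve(1e3, 1.0, 0.2) == pytest.approx(100.0)
        assert sigmoid_curve(-1e3, 1.0, 0.2) == pytest.approx(50.0)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_fit([0.1, 0.5, 1.0], [75.0, 75.0, 75.0])
        with pytest.raises(ValueError):
            sigmoid_fit([0.1, 0.5], [60.0, 80.0])
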