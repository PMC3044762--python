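"""Integrator correctness: gating, decay, fixed points, the analytic LIF
interspike interval, Poisson input statistics, and determinism."""

import numpy as np
import pytest

import pairnet as pn
from pairnet.dynamics import (IntegrationConfig, LayerState, NoiseConfig,
                              SpikeRecord, SynapseKinetics,
                              generate_poisson_inputs, nmda_gating, run_trial)

from conftest import zero_weights


class TestNmdaGating:
    def test_reference_values(self):
        assert nmda_gating(0.0) == pytest.approx(0.781, abs=1e-3)
        assert nmda_gating(-70.0) == pytest.approx(0.0445, abs=1e-3)

    def test_monotone_and_saturating(self):
        v = np.linspace(-100, 200, 500)
        g = nmda_gating(v)
        assert (np.diff(g) > 0).all()
        assert nmda_gating(1e4) == pytest.approx(1.0)
        assert 0 < nmda_gating(-1e2) < 1


class TestPoissonInputs:
    def test_active_groups_only(self):
        ens = pn.build_input_ensemble(10, 1 / 3, 0)
        rec = generate_poisson_inputs(ens, ("C", "D"), 1000.0, 3)
        silent = np.flatnonzero(~ens.active_groups(("C", "D")))
        assert not np.isin(rec.ids, silent).any()

    def test_group_rate(self):
        # 10 groups of 48 Hz: expected 48 spikes per group per second
        ens = pn.build_input_ensemble(10, 1 / 3, 0)
        counts = []
        for s in range(20):
            rec = generate_poisson_inputs(ens, ("A", "B"), 1000.0, s)
            counts.append(rec.ids.size / 20)  # 20 active groups
        assert abs(np.mean(counts) - 48.0) < 3 * np.sqrt(48 / 20 / 20)

    def test_times_sorted_within_duration(self):
        ens = pn.build_input_ensemble(6, 1 / 3, 0)
        rec = generate_poisson_inputs(ens, ("A", "D"), 500.0, 1)
        assert (np.diff(rec.times) >= 0).all()
        assert rec.times.min() >= 0 and rec.times.max() < 500.0

    def test_determinism(self):
        ens = pn.build_input_ensemble(6, 1 / 3, 0)
        a = generate_poisson_inputs(ens, ("A", "B"), 1000.0, 7)
        b = generate_poisson_inputs(ens, ("A", "B"), 1000.0, 7)
        np.testing.assert_array_equal(a.ids, b.ids)
        np.testing.assert_array_equal(a.times, b.times)

    def test_bad_pair_rejected(self):
        ens = pn.build_input_ensemble(6, 1 / 3, 0)
        with pytest.raises(ValueError):
            generate_poisson_inputs(ens, ("A",), 100.0, 0)
        with pytest.raises(ValueError):
            generate_poisson_inputs(ens, ("A", "B", "C"), 100.0, 0)


class TestIntegration:
    def test_rest_is_fixed_point(self, tiny_network, desk_integ, no_noise,
                                 empty_inputs):
        net = zero_weights(tiny_network)
        res = run_trial(net, empty_inputs, integ=desk_integ, noise=no_noise,
                        noise_rng=np.random.default_rng(0))
        assert res.spikes_e.ids.size == 0 and res.spikes_i.ids.size == 0
        np.testing.assert_allclose(
            res.state.v[:40], net.params_e["leak_reversal"], atol=1e-9)

    def test_conductance_decays_by_e_over_tau(self, tiny_network, desk_integ,
                                              no_noise):
        net = zero_weights(tiny_network)
        n = 50
        state = LayerState(
            v=np.full(n, -70.0), g_ampa=np.ones(n), g_nmda=np.ones(n),
            g_gaba=np.ones(n), g_ref=np.zeros(n), v_th=np.full(n, -50.0))
        integ = IntegrationConfig(dt=0.05, cue_ms=2.0, relax_ms=0.0)
        empty = SpikeRecord(np.empty(0, dtype=np.int64), np.empty(0), "input", 2.0)
        res = run_trial(net, empty, integ=integ, noise=no_noise,
                        noise_rng=np.random.default_rng(0), state=state)
        # after 2 ms: AMPA (tau 2 ms) down by e; GABA (tau 10) and NMDA (tau 100)
        assert res.state.g_ampa[0] == pytest.approx(np.exp(-1.0), rel=1e-6)
        assert res.state.g_gaba[0] == pytest.approx(np.exp(-0.2), rel=1e-6)
        assert res.state.g_nmda[0] == pytest.approx(np.exp(-0.02), rel=1e-6)

    @staticmethod
    def _constant_drive_trial(dt, g_drive=35.0, cue_ms=200.0):
        """Hard-reset homogeneous LIF under constant AMPA conductance."""
        cfg = pn.NetworkConfig(n_associative=50, regime="homogeneous_cells",
                               master_seed=1)
        net = zero_weights(pn.build_associative_network(cfg))
        kin = SynapseKinetics(tau_ampa=1e12, threshold_jump=0.0)
        n = 50
        state = LayerState(
            v=np.full(n, -70.0), g_ampa=np.full(n, g_drive),
            g_nmda=np.zeros(n), g_gaba=np.zeros(n), g_ref=np.zeros(n),
            v_th=np.full(n, -50.0))
        integ = IntegrationConfig(dt=dt, cue_ms=cue_ms, relax_ms=0.0,
                                  hard_reset=True)
        empty = SpikeRecord(np.empty(0, dtype=np.int64), np.empty(0), "input",
                            cue_ms)
        noise = NoiseConfig(voltage_noise_on=False, conductance_noise_on=False)
        return run_trial(net, empty, integ=integ, kinetics=kin, noise=noise,
                         noise_rng=np.random.default_rng(0), state=state)

    def test_noise_free_lif_matches_analytic_isi(self):
        # V_inf = (gL*VL + gA*0)/(gL+gA) = -35 mV; tau_eff = C/(gL+gA) = 5 ms
        # ISI = tau_eff * ln((V_inf - V_reset)/(V_inf - V_th)) with reset -60
        res = self._constant_drive_trial(dt=0.01)
        isi_expected = 5.0 * np.log((-35.0 + 60.0) / (-35.0 + 50.0))
        times = res.spikes_e.times_of(0)
        isis = np.diff(times)
        assert isis.size > 10
        assert np.all(np.abs(isis - isi_expected) <= 0.02 + 1e-9)

    def test_spike_count_stable_under_dt_halving(self):
        a = self._constant_drive_trial(dt=0.05)
        b = self._constant_drive_trial(dt=0.025)
        ca = np.bincount(a.spikes_e.ids, minlength=40)
        cb = np.bincount(b.spikes_e.ids, minlength=40)
        assert np.abs(ca - cb).max() <= 1

    def test_periodic_spiking_under_constant_drive(self):
        res = self._constant_drive_trial(dt=0.01)
        isis = np.diff(res.spikes_e.times_of(3))
        assert np.ptp(isis) <= 0.02 + 1e-9

    def test_dynamic_threshold_bounded(self, tiny_network, desk_integ):
        cfg = tiny_network.config
        spikes = generate_poisson_inputs(tiny_network.ensemble, ("A", "B"),
                                         desk_integ.cue_ms, 0)
        res = run_trial(tiny_network, spikes, integ=desk_integ,
                        noise_rng=np.random.default_rng(0))
        assert (res.state.v_th <= 150.0).all()
        base = np.concatenate([tiny_network.params_e["threshold_base"],
                               tiny_network.params_i["threshold_base"]])
        assert (res.state.v_th >= base - 1e-9).all()

    def test_trial_determinism(self, tiny_network, desk_integ):
        ens = tiny_network.ensemble
        out = []
        for _ in range(2):
            spikes = generate_poisson_inputs(ens, ("A", "B"), desk_integ.cue_ms, 5)
            res = run_trial(tiny_network, spikes, integ=desk_integ,
                            noise_rng=np.random.default_rng(5))
            out.append(res)
        np.testing.assert_array_equal(out[0].spikes_e.ids, out[1].spikes_e.ids)
        np.testing.assert_array_equal(out[0].spikes_e.times, out[1].spikes_e.times)
        np.testing.assert_array_equal(out[0].rates_i, out[1].rates_i)
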