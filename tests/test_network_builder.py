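"""Construction statistics of the random heterogeneous networks."""

import numpy as np
import pytest

import pairnet as pn
from pairnet.network_builder import (ConfigurationError, GROUP_COUNTS,
                                     INPUT_PROBABILITIES, build_input_ensemble,
                                     grid_configs, sample_cell_params)


@pytest.fixture(scope="module")
def default_net():
    return pn.build_associative_network(pn.NetworkConfig(master_seed=2))


class TestCellParams:
    def test_heterogeneity_bounds(self):
        df = sample_cell_params(320, "excitatory", "associative", 0)
        assert df["refractory_time_constant"].between(1.75, 2.25).all()
        assert df["leak_reversal"].between(-72.5, -67.5).all()
        assert df["membrane_time_constant"].between(9.25, 10.75).all()
        assert df["threshold_base"].between(-52, -48).all()

    def test_zero_spread_equals_mean(self):
        df = sample_cell_params(1, "excitatory", "decision", 0)
        assert df.loc[0, "membrane_time_constant"] == 20.0
        assert df.loc[0, "threshold_base"] == -48.0

    def test_large_sample_mean(self):
        # law of large numbers on uniform(-72.5, -67.5)
        df = sample_cell_params(10_000, "excitatory", "associative", 1)
        assert abs(df["leak_reversal"].mean() + 70.0) < 0.1

    def test_inhibitory_refractory_faster(self):
        df = sample_cell_params(100, "inhibitory", "associative", 0)
        assert df["refractory_time_constant"].between(0.75, 1.25).all()

    def test_high_threshold_regimes_raise_leak(self):
        for regime, mean in [("high_threshold_40", 40.0), ("high_threshold_50", 50.0)]:
            df = sample_cell_params(500, "excitatory", "associative", 0, regime)
            assert df["leak_conductance"].between(mean - 1, mean + 1).all()

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_cell_params(10, "modulatory", "associative", 0)


class TestAssociativeNetwork:
    def test_population_sizes(self, default_net):
        assert default_net.params_e.shape[0] == 320
        assert default_net.params_i.shape[0] == 80

    def test_block_densities(self, default_net):
        ee = default_net.blocks["ee"].mask.adjacency
        assert 0.08 < ee.mean() < 0.12
        ie = default_net.blocks["ie"].mask.adjacency
        assert 0.22 < ie.mean() < 0.28
        # all-to-all I->I excluding self-connections
        assert default_net.blocks["ii"].mask.adjacency.sum() == 80 * 79

    def test_no_self_connections(self, default_net):
        assert not np.diag(default_net.blocks["ee"].mask.adjacency).any()
        assert not np.diag(default_net.blocks["ii"].mask.adjacency).any()

    def test_feedforward_inhibition_standard(self, default_net):
        assert "ei" not in default_net.blocks

    def test_recurrent_inhibition_regime(self):
        net = pn.build_associative_network(
            pn.NetworkConfig(regime="recurrent_inhibition", master_seed=2))
        assert 0.20 < net.blocks["ei"].mask.adjacency.mean() < 0.30

    def test_weight_jitter_within_half_width(self, default_net):
        for name, blk in default_net.blocks.items():
            w = blk.weights[blk.mask.adjacency]
            assert w.min() >= 0.5 * blk.w0 - 1e-12, name
            assert w.max() <= 1.5 * blk.w0 + 1e-12, name

    def test_plasticity_tags(self, default_net):
        tags = {k: b.plasticity_tag for k, b in default_net.blocks.items()}
        assert tags["ee"] == "pair_stdp" and tags["in_e"] == "pair_stdp"
        assert tags["ie"] == "ltpi"
        assert tags["ii"] == "static" and tags["in_i"] == "static"

    def test_size_scaling_preserves_total_drive(self):
        half = pn.build_associative_network(
            pn.NetworkConfig(n_associative=200, master_seed=2))
        assert half.blocks["ee"].w0 == pytest.approx(0.05 * 2)
        # input weights are not size-scaled
        assert half.blocks["in_e"].w0 == pytest.approx(0.05)

    def test_homogeneous_inputs_all_to_all(self):
        net = pn.build_associative_network(
            pn.NetworkConfig(regime="homogeneous_inputs", master_seed=2))
        assert net.ensemble.mask_e.all() and net.ensemble.mask_i.all()

    def test_inhibition_x4_regime(self):
        net = pn.build_associative_network(
            pn.NetworkConfig(regime="inhibition_x4", master_seed=2))
        assert net.blocks["ie"].w0 == pytest.approx(4 * 0.05)

    def test_build_is_reproducible(self):
        a = pn.build_associative_network(pn.NetworkConfig(master_seed=5))
        b = pn.build_associative_network(pn.NetworkConfig(master_seed=5))
        for k in a.blocks:
            np.testing.assert_array_equal(a.blocks[k].weights, b.blocks[k].weights)
        assert a.params_e.equals(b.params_e)


class TestInputEnsemble:
    def test_rate_per_group(self):
        ens = build_input_ensemble(10, 1 / 3, 0)
        assert ens.rate_per_group == pytest.approx(48.0)
        assert build_input_ensemble(2, 1 / 3, 0).rate_per_group == pytest.approx(240.0)

    def test_expected_connections(self):
        ens = build_input_ensemble(20, 1 / 20, 0, n_e=320)
        per_group = ens.mask_e.sum(axis=1)
        assert abs(per_group.mean() - 16.0) < 3 * np.sqrt(16 * 0.95)

    def test_total_rate_conserved(self):
        for g in GROUP_COUNTS:
            ens = build_input_ensemble(g, 1 / 3, 0)
            assert g * ens.rate_per_group == pytest.approx(480.0)

    def test_active_groups_for_pair(self):
        ens = build_input_ensemble(4, 1 / 3, 0)
        act = ens.active_groups(("A", "B"))
        assert act.sum() == 8
        assert set(ens.group_stimulus[act]) == {"A", "B"}

    def test_nonstandard_values_rejected(self):
        with pytest.raises(ConfigurationError):
            build_input_ensemble(3, 1 / 3, 0)
        with pytest.raises(ConfigurationError):
            build_input_ensemble(10, 0.4, 0)
        # explicit override allows exploration off the stated grid
        ens = build_input_ensemble(3, 0.4, 0, allow_nonstandard=True)
        assert ens.n_groups == 12


class TestDecisionNetwork:
    def test_pool_sizes(self):
        dec = pn.build_decision_network(pn.NetworkConfig(master_seed=2))
        assert (dec.pool_of_e == 0).sum() == 200 and (dec.pool_of_e == 1).sum() == 200
        assert (dec.pool_of_i == 0).sum() == 50 and (dec.pool_of_i == 1).sum() == 50

    def test_cross_inhibition_topology(self):
        dec = pn.build_decision_network(pn.NetworkConfig(master_seed=2))
        ie = dec.blocks["ie_cross"].mask.adjacency
        same_pool = dec.pool_of_i[:, None] == dec.pool_of_e[None, :]
        assert not ie[same_pool].any()
        assert ie[~same_pool].all()

    def test_afferent_strengths(self):
        cfg_dense = pn.NetworkConfig(input_probability=1 / 3, master_seed=2)
        cfg_sparse = pn.NetworkConfig(input_probability=1 / 20, master_seed=2)
        assert pn.build_decision_network(cfg_dense, trained=True).afferent.w0 == 0.075
        assert pn.build_decision_network(cfg_sparse, trained=True).afferent.w0 == 0.075
        assert pn.build_decision_network(cfg_sparse, trained=False).afferent.w0 == 0.125
        assert pn.build_decision_network(cfg_dense, trained=False).afferent.w0 == 0.075


class TestGridConfigs:
    def test_grid_size_and_distinctness(self):
        configs = grid_configs("standard", master_seed=0)
        assert len(configs) == 25
        cells = {(c.groups_per_stimulus, round(1 / c.input_probability)) for c in configs}
        assert len(cells) == 25

    def test_grid_covers_stated_sets(self):
        configs = grid_configs("standard", master_seed=0)
        assert {c.groups_per_stimulus for c in configs} == set(GROUP_COUNTS)
        probs = {round(1 / c.input_probability) for c in configs}
        assert probs == {round(1 / p) for p in INPUT_PROBABILITIES}

    def test_grid_seed_determinism(self):
        a = grid_configs("standard", master_seed=9)
        b = grid_configs("standard", master_seed=9)
        assert [c.master_seed for c in a] == [c.master_seed for c in b]
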