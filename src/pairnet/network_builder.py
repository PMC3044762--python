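"""Random heterogeneous network construction.

This module is the study's synthetic-data generator.  It builds

* the associative layer: 400 leaky integrate-and-fire cells (4:1 E:I) with
  uniformly heterogeneous intrinsic parameters, sparse-random recurrent
  excitation (10%), feedforward inhibition (I->E 25%, I->I all-to-all) and
  uniformly jittered initial weights W0 +/- 50%;
* the input ensemble: four stimuli (A, B, C, D), each carried by G
  independent Poisson groups firing at 480/G Hz, projecting with a grid
  probability p in {1/2, 1/3, 1/5, 1/10, 1/20} onto every associative cell;
* the decision layer: two winner-take-all pools (200 E + 50 I each) with
  all-to-all within-pool excitation and direct cross-inhibition, receiving
  all-to-all afferents from the associative excitatory cells.

Sweeping p and G in {2, 4, 6, 10, 20} yields the 25-network grid over input
sparseness and input correlation that the whole study runs on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rng as _rng

INPUT_PROBABILITIES = (1 / 2, 1 / 3, 1 / 5, 1 / 10, 1 / 20)
GROUP_COUNTS = (2, 4, 6, 10, 20)
STIMULI = ("A", "B", "C", "D")
TOTAL_INPUT_RATE_HZ = 480.0  # per active stimulus, split over its groups

REGIMES = (
    "standard",
    "high_threshold_40",
    "high_threshold_50",
    "inhibition_x4",
    "low_goal_rate",
    "recurrent_inhibition",
    "homogeneous_inputs",
    "homogeneous_EE",
    "homogeneous_IE",
    "homogeneous_cells",
)

THRESHOLD_MAX_MV = 150.0

# (layer, cell_class) -> field -> (mean, half-width of the uniform spread)
_PARAM_TABLE = {
    ("associative", "excitatory"): {
        "leak_reversal": (-70.0, 2.5),
        "membrane_time_constant": (10.0, 0.75),
        "leak_conductance": (35.0, 1.0),
        "threshold_base": (-50.0, 2.0),
        "reset_voltage": (-60.0, 2.0),
        "refractory_time_constant": (2.0, 0.25),
    },
    ("associative", "inhibitory"): {
        "leak_reversal": (-70.0, 2.5),
        "membrane_time_constant": (10.0, 0.75),
        "leak_conductance": (35.0, 1.0),
        "threshold_base": (-50.0, 2.0),
        "reset_voltage": (-60.0, 2.0),
        "refractory_time_constant": (1.0, 0.25),
    },
    # decision layer is homogeneous (spread 0 everywhere)
    ("decision", "excitatory"): {
        "leak_reversal": (-70.0, 0.0),
        "membrane_time_constant": (20.0, 0.0),
        "leak_conductance": (35.0, 0.0),
        "threshold_base": (-48.0, 0.0),
        "reset_voltage": (-55.0, 0.0),
        "refractory_time_constant": (2.0, 0.0),
    },
    ("decision", "inhibitory"): {
        "leak_reversal": (-70.0, 0.0),
        "membrane_time_constant": (10.0, 0.0),
        "leak_conductance": (30.0, 0.0),
        "threshold_base": (-50.0, 0.0),
        "reset_voltage": (-55.0, 0.0),
        "refractory_time_constant": (1.0, 0.0),
    },
}


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside the study's stated sets."""


@dataclass(frozen=True)
class NetworkConfig:
    """One grid cell of the study: network size, input statistics, regime."""

    n_associative: int = 400
    input_probability: float = 1 / 3
    groups_per_stimulus: int = 6
    regime: str = "standard"
    master_seed: int = 0
    w0: float = 0.05  # initial mean recurrent weight, +/-50% uniform
    dw0_trained: float = 0.075  # associative->decision afferent weight
    dw0_sparse_untrained: float = 0.125  # untrained networks at p = 1/10, 1/20
    decision_w0: float = 0.25
    allow_nonstandard_grid: bool = False

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ConfigurationError(
                f"unknown regime {self.regime!r}; allowed: {REGIMES}")
        if self.n_associative % 5 != 0 or self.n_associative <= 0:
            raise ConfigurationError(
                "n_associative must be a positive multiple of 5 (4:1 E:I split)")
        if not self.allow_nonstandard_grid:
            if self.groups_per_stimulus not in GROUP_COUNTS:
                raise ConfigurationError(
                    f"groups_per_stimulus={self.groups_per_stimulus} not in {GROUP_COUNTS}")
            if not any(np.isclose(self.input_probability, p) for p in INPUT_PROBABILITIES):
                raise ConfigurationError(
                    f"input_probability={self.input_probability} not in "
                    f"{{1/2, 1/3, 1/5, 1/10, 1/20}}")

    @property
    def n_excitatory(self) -> int:
        return self.n_associative * 4 // 5

    @property
    def n_inhibitory(self) -> int:
        return self.n_associative // 5

    @property
    def recurrent_weight_scale(self) -> float:
        # recurrent strength scales with network size so that the total
        # recurrent drive per cell is invariant under changes of n
        return 400.0 / self.n_associative


@dataclass
class ConnectivityMask:
    presynaptic_population: str
    postsynaptic_population: str
    adjacency: np.ndarray  # bool, shape (n_pre, n_post)
    connection_probability: float


@dataclass
class SynapseBlock:
    """A (pre-population -> post-population) weight block.

    ``weights`` is dense with zeros off the mask; ``w0`` is the block's
    initial mean strength and anchors the global bound [0, 20*w0].
    """

    mask: ConnectivityMask
    weights: np.ndarray
    w0: float
    plasticity_tag: str  # static | pair_stdp | triplet_stdp | ltpi | reward

    @property
    def upper_bound(self) -> float:
        return 20.0 * self.w0


@dataclass
class InputEnsemble:
    groups_per_stimulus: int
    input_probability: float
    mask_e: np.ndarray  # bool, (4G, n_E)
    mask_i: np.ndarray  # bool, (4G, n_I)
    group_stimulus: np.ndarray  # str, (4G,) entry in STIMULI

    @property
    def n_groups(self) -> int:
        return 4 * self.groups_per_stimulus

    @property
    def rate_per_group(self) -> float:
        return TOTAL_INPUT_RATE_HZ / self.groups_per_stimulus

    def active_groups(self, stimulus_pair) -> np.ndarray:
        """Boolean vector over groups for a 2-stimulus pair like ('A', 'B')."""
        pair = set(stimulus_pair)
        if len(pair) != 2 or not pair <= set(STIMULI):
            raise ValueError(f"stimulus pair must be two of {STIMULI}, got {stimulus_pair}")
        return np.isin(self.group_stimulus, sorted(pair))


@dataclass
class NetworkInstance:
    config: NetworkConfig
    params_e: pd.DataFrame
    params_i: pd.DataFrame
    ensemble: InputEnsemble
    blocks: dict  # name -> SynapseBlock
    seeds: dict  # randomness source -> integer seed actually used


@dataclass
class DecisionInstance:
    config: NetworkConfig
    params_e: pd.DataFrame  # 400 rows, pool column
    params_i: pd.DataFrame  # 100 rows, pool column
    pool_of_e: np.ndarray  # 0 = Release, 1 = Hold
    pool_of_i: np.ndarray
    blocks: dict  # within-pool / cross blocks
    afferent: SynapseBlock  # associative E -> decision E, all-to-all
    seeds: dict


# ---------------------------------------------------------------------------
# cell parameters

def sample_cell_params(n: int, cell_class: str, layer: str,
                       seed_or_rng, regime: str = "standard") -> pd.DataFrame:
    """Draw ``n`` cells' intrinsic parameters, each field independently
    uniform in [mean - spread, mean + spread] for its (layer, class) entry.

    Decision-layer cells and the ``homogeneous_cells`` regime have zero
    spread.  High-threshold regimes raise the associative leak conductance
    mean to 40 or 50 uS, which raises the effective firing threshold.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    key = (layer, cell_class)
    if key not in _PARAM_TABLE:
        raise ConfigurationError(
            f"unknown (layer, cell_class) = {key}; allowed: {sorted(_PARAM_TABLE)}")
    table = dict(_PARAM_TABLE[key])
    if layer == "associative":
        if regime == "high_threshold_40":
            table["leak_conductance"] = (40.0, 1.0)
        elif regime == "high_threshold_50":
            table["leak_conductance"] = (50.0, 1.0)
    gen = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    homogeneous = (layer == "decision") or (regime == "homogeneous_cells")
    cols = {}
    for name, (mean, spread) in table.items():
        if homogeneous or spread == 0.0:
            cols[name] = np.full(n, mean)
        else:
            cols[name] = gen.uniform(mean - spread, mean + spread, size=n)
    df = pd.DataFrame(cols)
    df["threshold_max"] = THRESHOLD_MAX_MV
    df["cell_class"] = cell_class
    df["layer"] = layer
    return df


# ---------------------------------------------------------------------------
# connectivity

def _random_mask(gen: np.random.Generator, n_pre: int, n_post: int,
                 p: float, no_self: bool = False) -> np.ndarray:
    adj = gen.random((n_pre, n_post)) < p
    if no_self:
        np.fill_diagonal(adj, False)
    return adj


def _all_to_all(n_pre: int, n_post: int, no_self: bool = False) -> np.ndarray:
    adj = np.ones((n_pre, n_post), dtype=bool)
    if no_self:
        np.fill_diagonal(adj, False)
    return adj


def _jittered_weights(gen: np.random.Generator, mask: np.ndarray,
                      w0: float) -> np.ndarray:
    w = np.zeros(mask.shape)
    k = int(mask.sum())
    w[mask] = gen.uniform(0.5 * w0, 1.5 * w0, size=k)
    return w


def _make_block(gen, pre: str, post: str, adj: np.ndarray, p: float,
                w0: float, tag: str) -> SynapseBlock:
    mask = ConnectivityMask(pre, post, adj, p)
    return SynapseBlock(mask, _jittered_weights(gen, adj, w0), w0, tag)


def build_input_ensemble(groups_per_stimulus: int, probability: float,
                         seed_or_rng, n_e: int = 320, n_i: int = 80,
                         homogeneous: bool = False,
                         allow_nonstandard: bool = False) -> InputEnsemble:
    """Projection masks for 4 x G independent input groups.

    Each group targets every associative cell (E and I alike) independently
    with the grid probability; in the ``homogeneous_inputs`` regime every
    group connects to every cell.
    """
    if not allow_nonstandard:
        if groups_per_stimulus not in GROUP_COUNTS:
            raise ConfigurationError(
                f"groups_per_stimulus={groups_per_stimulus} not in {GROUP_COUNTS}")
        if not any(np.isclose(probability, p) for p in INPUT_PROBABILITIES):
            raise ConfigurationError(
                f"probability={probability} not in {{1/2, 1/3, 1/5, 1/10, 1/20}}")
    gen = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    n_groups = 4 * groups_per_stimulus
    group_stimulus = np.repeat(list(STIMULI), groups_per_stimulus)
    if homogeneous:
        mask_e = np.ones((n_groups, n_e), dtype=bool)
        mask_i = np.ones((n_groups, n_i), dtype=bool)
    else:
        mask_e = gen.random((n_groups, n_e)) < probability
        mask_i = gen.random((n_groups, n_i)) < probability
    return InputEnsemble(groups_per_stimulus, probability, mask_e, mask_i,
                         group_stimulus)


def build_associative_network(config: NetworkConfig) -> NetworkInstance:
    """Assemble one random associative-layer instantiation.

    Block densities: E->E 10% sparse-random, I->E 25% sparse-random,
    I->I all-to-all; inhibition is feedforward only, so E->I exists (25%)
    only in the ``recurrent_inhibition`` regime.  Plasticity capability:
    E->E and input->E carry STDP, I->E carries LTPi, everything else is
    static.  Recurrent weights carry the 400/n size scaling.
    """
    n_e, n_i = config.n_excitatory, config.n_inhibitory
    ms = config.master_seed
    seeds = {
        "structure": _rng.child_seed(ms, _rng.STRUCTURE),
        "cell_params": _rng.child_seed(ms, _rng.CELL_PARAMS),
        "weights": _rng.child_seed(ms, _rng.WEIGHTS),
    }
    g_struct = np.random.default_rng(seeds["structure"])
    g_par = np.random.default_rng(seeds["cell_params"])
    g_w = np.random.default_rng(seeds["weights"])

    params_e = sample_cell_params(n_e, "excitatory", "associative", g_par, config.regime)
    params_i = sample_cell_params(n_i, "inhibitory", "associative", g_par, config.regime)

    ensemble = build_input_ensemble(
        config.groups_per_stimulus, config.input_probability, g_struct,
        n_e=n_e, n_i=n_i, homogeneous=(config.regime == "homogeneous_inputs"),
        allow_nonstandard=config.allow_nonstandard_grid)

    w_rec = config.w0 * config.recurrent_weight_scale
    blocks = {}
    ee_adj = (_all_to_all(n_e, n_e, no_self=True)
              if config.regime == "homogeneous_EE"
              else _random_mask(g_struct, n_e, n_e, 0.10, no_self=True))
    blocks["ee"] = _make_block(g_w, "E", "E", ee_adj, 0.10, w_rec, "pair_stdp")

    ie_w0 = w_rec * (4.0 if config.regime == "inhibition_x4" else 1.0)
    ie_adj = (_all_to_all(n_i, n_e)
              if config.regime == "homogeneous_IE"
              else _random_mask(g_struct, n_i, n_e, 0.25))
    blocks["ie"] = _make_block(g_w, "I", "E", ie_adj, 0.25, ie_w0, "ltpi")

    blocks["ii"] = _make_block(g_w, "I", "I", _all_to_all(n_i, n_i, no_self=True),
                               1.0, w_rec, "static")
    if config.regime == "recurrent_inhibition":
        blocks["ei"] = _make_block(g_w, "E", "I",
                                   _random_mask(g_struct, n_e, n_i, 0.25),
                                   0.25, w_rec, "static")

    # input weights are not size-scaled: the input ensemble is external
    blocks["in_e"] = _make_block(g_w, "input", "E", ensemble.mask_e,
                                 config.input_probability, config.w0, "pair_stdp")
    blocks["in_i"] = _make_block(g_w, "input", "I", ensemble.mask_i,
                                 config.input_probability, config.w0, "static")

    return NetworkInstance(config, params_e, params_i, ensemble, blocks, seeds)


def build_decision_network(config: NetworkConfig,
                           trained: bool = True) -> DecisionInstance:
    """Two-pool winner-take-all circuit (500 cells, 4:1 E:I).

    Within-pool connections (E->E and E->I) are all-to-all at the decision
    W0; cross-inhibition runs directly from each pool's inhibitory cells to
    the opposing pool's excitatory cells.  Afferents from every associative
    excitatory cell to every decision excitatory cell are uniform at
    DW0 = 0.075 for trained networks; untrained sparse networks
    (p = 1/10, 1/20) use DW0 = 0.125 so a single strength can drive them.
    """
    n_pool_e, n_pool_i = 200, 50
    n_e, n_i = 2 * n_pool_e, 2 * n_pool_i
    seeds = {"decision": _rng.child_seed(config.master_seed, _rng.DECISION)}

    params_e = sample_cell_params(n_e, "excitatory", "decision", seeds["decision"])
    params_i = sample_cell_params(n_i, "inhibitory", "decision", seeds["decision"])
    pool_of_e = np.repeat([0, 1], n_pool_e)
    pool_of_i = np.repeat([0, 1], n_pool_i)
    params_e["pool"] = pool_of_e
    params_i["pool"] = pool_of_i

    w0 = config.decision_w0
    same_e = pool_of_e[:, None] == pool_of_e[None, :]
    ee_adj = same_e.copy()
    np.fill_diagonal(ee_adj, False)
    ei_adj = pool_of_e[:, None] == pool_of_i[None, :]
    ie_adj = pool_of_i[:, None] != pool_of_e[None, :]  # cross-inhibition only

    def uniform_block(pre, post, adj, p):
        w = np.where(adj, w0, 0.0)
        return SynapseBlock(ConnectivityMask(pre, post, adj, p), w, w0, "static")

    blocks = {
        "ee_pool": uniform_block("dE", "dE", ee_adj, 1.0),
        "ei_pool": uniform_block("dE", "dI", ei_adj, 1.0),
        "ie_cross": uniform_block("dI", "dE", ie_adj, 1.0),
    }

    sparse = config.input_probability <= 1 / 10 + 1e-9
    dw0 = config.dw0_trained if trained else (
        config.dw0_sparse_untrained if sparse else config.dw0_trained)
    aff_adj = np.ones((config.n_excitatory, n_e), dtype=bool)
    afferent = SynapseBlock(ConnectivityMask("E", "dE", aff_adj, 1.0),
                            np.full(aff_adj.shape, dw0), dw0, "reward")
    return DecisionInstance(config, params_e, params_i, pool_of_e, pool_of_i,
                            blocks, afferent, seeds)


def grid_configs(regime: str = "standard", master_seed: int = 0,
                 n_associative: int = 400) -> list[NetworkConfig]:
    """The 25 grid-cell configurations (5 probabilities x 5 group counts),
    each with its own seed derived from the master seed."""
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown regime {regime!r}")
    configs = []
    idx = 0
    for p in INPUT_PROBABILITIES:
        for g in GROUP_COUNTS:
            configs.append(NetworkConfig(
                n_associative=n_associative, input_probability=p,
                groups_per_stimulus=g, regime=regime,
                master_seed=_rng.child_seed(master_seed, _rng.GRID, idx)))
            idx += 1
    return configs
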