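"""Biconditional (XOR) discrimination task and training loops.

Two of four stimuli (A, B, C, D) are shown together each trial.  A+B and
C+D demand "Release"; A+D and C+B demand "Hold" -- an XOR mapping over
stimulus identities, so no single-stimulus response can solve the task.

``train_network`` runs the full closed loop: Poisson inputs -> associative
trial with the condition's plasticity engines -> decision trial ->
dopamine reward update -> homeostasis -> bound enforcement, with periodic
frozen-plasticity probe blocks that estimate each cell's four pair rates
for the selectivity metric.  ``run_condition_grid`` sweeps grid cells and
conditions at configurable (reduced or full) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import rng as _rng
from .decision import (RewardRuleConfig, UrgencyConfig, da_reward_update,
                       run_decision)
from .dynamics import (IntegrationConfig, NoiseConfig, SynapseKinetics,
                       generate_poisson_inputs, run_trial)
from .metrics import network_selectivity, performance_bins
from .network_builder import (DecisionInstance, NetworkConfig, NetworkInstance,
                              build_associative_network, build_decision_network,
                              grid_configs)
from .plasticity import (HomeostasisConfig, draw_goal_rates, enforce_bounds,
                         homeostasis_step, make_engines)

PAIRS = (("A", "B"), ("A", "D"), ("C", "B"), ("C", "D"))
PAIR_NAMES = ("A+B", "A+D", "C+B", "C+D")
CONDITIONS = ("initial", "pair_stdp", "triplet_stdp", "ltpi",
              "ltpi+pair_stdp", "ltpi+triplet_stdp")

_PLASTIC_BLOCKS = ("ee", "ie", "in_e")


class ProtocolError(ValueError):
    pass


def correct_response(pair) -> str:
    """XOR mapping: A+B and C+D -> Release; A+D and C+B -> Hold."""
    key = frozenset(pair)
    mapping = {frozenset("AB"): "Release", frozenset("CD"): "Release",
               frozenset("AD"): "Hold", frozenset("CB"): "Hold"}
    if key not in mapping:
        raise ProtocolError(f"unknown stimulus pair {pair!r}")
    return mapping[key]


@dataclass(frozen=True)
class TrialSpec:
    index: int
    pair: tuple
    correct: str


def make_trial_sequence(n_trials: int, seed_or_rng) -> list[TrialSpec]:
    """Balanced pseudorandom order: blocks of four, one of each pair per
    block, shuffled within blocks, so |count(pair) - n/4| <= 1."""
    if n_trials <= 0:
        raise ProtocolError("n_trials must be positive")
    gen = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    order = []
    while len(order) < n_trials:
        block = gen.permutation(4)
        order.extend(block.tolist())
    order = order[:n_trials]
    return [TrialSpec(i, PAIRS[p], correct_response(PAIRS[p]))
            for i, p in enumerate(order)]


@dataclass
class ConditionSpec:
    """One training condition: which plasticity hooks run, for how long."""

    condition: str = "ltpi"
    n_trials: int = 800
    homeostasis: bool = True  # forced off for the 'initial' condition
    with_decision: bool = True
    reward_learning: bool = True

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ProtocolError(
                f"unknown condition {self.condition!r}; allowed: {CONDITIONS}")
        if self.condition == "initial":
            # 'initial' freezes the associative layer entirely; reward
            # plasticity on the decision afferents still trains, which is
            # how untrained-network performance is measured
            self.homeostasis = False


@dataclass
class ProbeResult:
    after_trial: int
    rates: np.ndarray  # (n_E, 4) mean cue rate per pair
    mean_selectivity: float
    rates_i: Optional[np.ndarray] = None  # (n_I, 4)


@dataclass
class TrainingLog:
    condition: str
    outcomes: list  # per-trial dicts
    probes: list  # ProbeResult
    initial_weights: dict  # block name -> copy at trial 0
    goal_rates_e: np.ndarray
    goal_rates_ie: np.ndarray

    def outcome_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.outcomes)

    @property
    def initial_selectivity(self) -> float:
        return self.probes[0].mean_selectivity

    @property
    def final_selectivity(self) -> float:
        return self.probes[-1].mean_selectivity


def probe_block(network: NetworkInstance, integ: IntegrationConfig,
                kinetics: SynapseKinetics, noise: NoiseConfig,
                seed: int, trials_per_pair: int = 5, state=None):
    """Frozen-plasticity probe: mean cue-window rate of every cell for each
    of the four pairs, averaged over ``trials_per_pair`` presentations.
    Returns (rates_e, rates_i), each (n_cells, 4)."""
    rates = np.zeros((network.config.n_excitatory, 4))
    rates_i = np.zeros((network.config.n_inhibitory, 4))
    for p, pair in enumerate(PAIRS):
        for k in range(trials_per_pair):
            gen_in = _rng.child_rng(seed, _rng.INPUTS, 10_000 + p * 100 + k)
            gen_noise = _rng.child_rng(seed, _rng.NOISE, 10_000 + p * 100 + k)
            spikes = generate_poisson_inputs(network.ensemble, pair,
                                             integ.cue_ms, gen_in)
            res = run_trial(network, spikes, engines=(), integ=integ,
                            kinetics=kinetics, noise=noise,
                            noise_rng=gen_noise, state=state)
            state = res.state
            rates[:, p] += res.rates_e
            rates_i[:, p] += res.rates_i
    return rates / trials_per_pair, rates_i / trials_per_pair


def train_network(network: NetworkInstance,
                  decision: Optional[DecisionInstance],
                  spec: ConditionSpec,
                  integ: IntegrationConfig = None,
                  kinetics: SynapseKinetics = None,
                  noise: NoiseConfig = None,
                  homeo: HomeostasisConfig = None,
                  reward: RewardRuleConfig = None,
                  urgency: UrgencyConfig = UrgencyConfig(),
                  probe_every: Optional[int] = 40,
                  probe_trials_per_pair: int = 5,
                  decision_dt: Optional[float] = None,
                  progress: bool = False) -> TrainingLog:
    """Train one network (and optionally its decision circuit) for
    ``spec.n_trials`` trials; deterministic given the network's master seed."""
    integ = integ or IntegrationConfig()
    kinetics = kinetics or SynapseKinetics()
    noise = noise or NoiseConfig()
    homeo = homeo or HomeostasisConfig(
        goal_e=4.0 if network.config.regime == "low_goal_rate" else 8.0)
    reward = reward or RewardRuleConfig()
    ms = network.config.master_seed
    cfg = network.config
    n_e = cfg.n_excitatory

    goal_rng = _rng.child_rng(ms, _rng.CELL_PARAMS, 999)
    goals_e = draw_goal_rates(n_e, homeo.goal_e, homeo.goal_spread, goal_rng)
    goals_ie = draw_goal_rates(n_e, homeo.goal_ie, homeo.goal_spread, goal_rng)

    trials = make_trial_sequence(spec.n_trials, _rng.child_rng(ms, _rng.TRIALS))
    engines = make_engines(spec.condition)
    initial_weights = {k: network.blocks[k].weights.copy() for k in _PLASTIC_BLOCKS
                       if k in network.blocks}

    log = TrainingLog(spec.condition, [], [], initial_weights, goals_e, goals_ie)
    cue_start = integ.relax_ms
    cue_end = integ.relax_ms + integ.cue_ms
    state = None

    def run_probe(after):
        rates, rates_i = probe_block(network, integ, kinetics, noise, seed=ms,
                                     trials_per_pair=probe_trials_per_pair)
        sel = network_selectivity(rates)
        log.probes.append(ProbeResult(after, rates, sel.mean, rates_i))

    run_probe(-1)
    for tr in trials:
        start_w = {k: network.blocks[k].weights.copy() for k in initial_weights}
        gen_in = _rng.child_rng(ms, _rng.INPUTS, tr.index)
        gen_noise = _rng.child_rng(ms, _rng.NOISE, tr.index)
        spikes_in = generate_poisson_inputs(network.ensemble, tr.pair,
                                            integ.cue_ms, gen_in)
        res = run_trial(network, spikes_in, engines=engines, integ=integ,
                        kinetics=kinetics, noise=noise, noise_rng=gen_noise,
                        state=state, trial=tr.index)
        state = res.state

        outcome_row = {"trial": tr.index, "pair": PAIR_NAMES[PAIRS.index(tr.pair)],
                       "correct_response": tr.correct,
                       "mean_rate_e": float(res.rates_e.mean())}
        if spec.with_decision and decision is not None:
            gen_dec = _rng.child_rng(ms, _rng.DECISION, tr.index)
            out = run_decision(decision, res.spikes_e, cue_start, cue_end,
                               noise_rng=gen_dec, noise=noise, urgency=urgency,
                               dt=decision_dt if decision_dt else integ.dt)
            out.correct = out.winner == tr.correct
            if spec.reward_learning:
                da_reward_update(decision, res.rates_e, out, reward)
            outcome_row.update({"choice": out.winner, "correct": out.correct,
                                "reward": out.reward,
                                "pool_rate_release": out.pool_rates[0],
                                "pool_rate_hold": out.pool_rates[1]})

        if spec.homeostasis:
            _apply_homeostasis(network, res.rates_e, homeo, goals_e, goals_ie)
        for name, start in start_w.items():
            blk = network.blocks[name]
            blk.weights[...] = enforce_bounds(blk.weights, start, blk.upper_bound)

        log.outcomes.append(outcome_row)
        if progress and (tr.index + 1) % 20 == 0:
            print(f"  trial {tr.index + 1}/{spec.n_trials} "
                  f"mean E rate {res.rates_e.mean():.1f} Hz")
        if probe_every and (tr.index + 1) % probe_every == 0:
            run_probe(tr.index)
    if not probe_every or spec.n_trials % probe_every != 0:
        run_probe(spec.n_trials - 1)
    return log


def _apply_homeostasis(network, rates_e, homeo, goals_e, goals_ie):
    for name in ("in_e", "ee"):
        blk = network.blocks[name]
        blk.weights[...] = homeostasis_step(blk.weights, rates_e, goals_e,
                                            homeo.eps_exc, "excitatory")
    blk = network.blocks["ie"]
    blk.weights[...] = homeostasis_step(blk.weights, rates_e, goals_ie,
                                        homeo.eps_ie, "inhibitory_to_e")


@dataclass
class GridResult:
    frame: pd.DataFrame  # one row per (grid cell, condition, instantiation)


def run_condition_grid(regime: str = "standard",
                       conditions: Sequence[str] = ("initial", "ltpi"),
                       n_trials: int = 800,
                       n_associative: int = 400,
                       instantiations: int = 4,
                       master_seed: int = 0,
                       subset: Optional[Sequence[tuple]] = None,
                       integ: IntegrationConfig = None,
                       probe_trials_per_pair: int = 5,
                       with_decision: bool = True,
                       progress: bool = False) -> GridResult:
    """Sweep grid cells x conditions x instantiations.

    ``subset`` restricts to (groups_per_stimulus, input_probability) tuples
    for desk-scale runs; reduced ``n_trials`` / ``n_associative`` scale the
    experiment down without changing its structure.
    """
    rows = []
    for cfg in grid_configs(regime, master_seed, n_associative):
        if subset is not None and not any(
                cfg.groups_per_stimulus == g and np.isclose(cfg.input_probability, p)
                for g, p in subset):
            continue
        for cond in conditions:
            for inst in range(instantiations):
                inst_cfg = replace(cfg, master_seed=_rng.child_seed(
                    cfg.master_seed, _rng.STRUCTURE, 7000 + inst))
                net = build_associative_network(inst_cfg)
                dec = build_decision_network(inst_cfg, trained=(cond != "initial")) \
                    if with_decision else None
                spec = ConditionSpec(condition=cond, n_trials=n_trials,
                                     with_decision=with_decision)
                log = train_network(net, dec, spec, integ=integ,
                                    probe_every=None,
                                    probe_trials_per_pair=probe_trials_per_pair,
                                    progress=progress)
                row = {"regime": regime, "condition": cond,
                       "instantiation": inst,
                       "groups": cfg.groups_per_stimulus,
                       "probability": cfg.input_probability,
                       "selectivity_initial": log.initial_selectivity,
                       "selectivity_final": log.final_selectivity}
                if with_decision:
                    flags = [o["correct"] for o in log.outcomes]
                    if len(flags) >= 40:
                        perf = performance_bins(flags)
                        row["performance_final"] = perf.final
                        row["classification"] = perf.classification
                    else:
                        row["performance_final"] = float(np.mean(flags))
                        row["classification"] = "short-run"
                rows.append(row)
    return GridResult(pd.DataFrame(rows))
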