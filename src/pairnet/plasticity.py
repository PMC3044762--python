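"""Synaptic learning rules and weight-bound enforcement.

Four rules act on the associative layer:

* pair STDP -- additive, all-to-all over spike pairs via exponential
  traces; LTP window tau+ = 16 ms with amplitude A+ = 1.20, LTD window
  tau- = 25 ms with amplitude A- = 0.80, scaled by dW = 0.005 per event;
* triplet STDP -- Pfister-Gerstner trace model with the all-to-all
  cortical amplitude set; recent postsynaptic spikes boost potentiation,
  recent presynaptic spikes boost depression, giving a rate-dependent
  LTD-to-LTP crossover near 20 Hz for uncorrelated Poisson trains;
* LTPi -- inhibitory-to-excitatory potentiation by idW = 0.005 per
  inhibitory spike, vetoed by any postsynaptic excitatory spike within
  +/-20 ms and gated by postsynaptic depolarization above a voltage
  threshold (-65 mV by default); never depresses;
* homeostasis -- trial-wise multiplicative postsynaptic scaling pushing
  each cell's cue-window mean rate toward its goal rate.

All rules respect a 50%-per-trial change cap relative to the trial-start
weight and the global bounds [0, 20 W0].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq


@dataclass
class PairSTDPConfig:
    a_plus: float = 1.20
    a_minus: float = 0.80
    tau_plus: float = 16.0  # ms
    tau_minus: float = 25.0
    dw: float = 0.005  # per-event scale


@dataclass
class TripletSTDPConfig:
    tau_2plus: float = 16.68  # ms, fast presynaptic trace
    tau_2minus: float = 33.7  # fast postsynaptic trace
    tau_y: float = 125.0  # slow postsynaptic trace
    tau_x: float = 101.0  # slow presynaptic trace
    a2_plus: float = 5e-10
    a2_minus: float = 7e-3
    a3_plus: float = 6.2e-3
    a3_minus: float = 2.3e-4
    dw: float = 0.005  # multiplies the amplitude set


@dataclass
class LTPiConfig:
    idw: float = 0.005  # per non-vetoed inhibitory spike
    veto_window: float = 20.0  # ms, symmetric
    depolarization_threshold: Optional[float] = -65.0  # mV; None disables gating


@dataclass
class HomeostasisConfig:
    eps_ie: float = 0.01  # inhibitory-to-excitatory synapses
    eps_exc: float = 0.0001  # input->E and E->E synapses
    goal_e: float = 8.0  # Hz (4 Hz in the low-goal-rate regime)
    goal_i: float = 8.0  # diagnostic only; I->I synapses are not plastic
    goal_ie: float = 8.0
    goal_spread: float = 5.0  # width of the per-cell uniform jitter


def draw_goal_rates(n: int, mean: float, spread: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-cell goal rates, uniform over a ``spread``-wide band about the mean."""
    return rng.uniform(mean - spread / 2.0, mean + spread / 2.0, size=n)


# ---------------------------------------------------------------------------
# pair STDP

def pair_stdp_delta(delta_t, config: PairSTDPConfig = PairSTDPConfig()):
    """Weight change for a single pre/post spike pair, delta_t = t_post - t_pre.

    Positive delta_t (pre before post) potentiates through the tau+ window;
    negative delta_t depresses through the tau- window; simultaneous spikes
    (delta_t = 0) produce no change.
    """
    dt = np.asarray(delta_t, dtype=float)
    out = np.where(
        dt > 0, config.dw * config.a_plus * np.exp(-dt / config.tau_plus),
        np.where(dt < 0,
                 -config.dw * config.a_minus * np.exp(dt / config.tau_minus),
                 0.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# triplet STDP

@dataclass
class TripletTraces:
    """Exponential spike traces of one pre/post pair (all-to-all update).

    ``r1``/``r2`` follow presynaptic spikes with tau_2+ / tau_x; ``o1``/``o2``
    follow postsynaptic spikes with tau_2- / tau_y.
    """

    config: TripletSTDPConfig
    r1: float = 0.0
    r2: float = 0.0
    o1: float = 0.0
    o2: float = 0.0
    t: float = 0.0

    def decay_to(self, t: float) -> None:
        if t < self.t:
            raise ValueError("traces are stale: time ran backwards")
        dt = t - self.t
        c = self.config
        self.r1 *= np.exp(-dt / c.tau_2plus)
        self.r2 *= np.exp(-dt / c.tau_x)
        self.o1 *= np.exp(-dt / c.tau_2minus)
        self.o2 *= np.exp(-dt / c.tau_y)
        self.t = t


def triplet_update_on_spike(event: str, t: float, traces: TripletTraces,
                            config: TripletSTDPConfig = None) -> float:
    """Process one spike of a single synapse's pre or post neuron.

    On a postsynaptic spike the weight potentiates by
    dW * r1 * (A2+ + A3+ * o2); on a presynaptic spike it depresses by
    dW * o1 * (A2- + A3- * r2); trace values are taken just before the
    spike's own increment.  Returns the signed weight change.
    """
    cfg = config or traces.config
    traces.decay_to(t)
    if event == "post":
        delta = cfg.dw * traces.r1 * (cfg.a2_plus + cfg.a3_plus * traces.o2)
        traces.o1 += 1.0
        traces.o2 += 1.0
    elif event == "pre":
        delta = -cfg.dw * traces.o1 * (cfg.a2_minus + cfg.a3_minus * traces.r2)
        traces.r1 += 1.0
        traces.r2 += 1.0
    else:
        raise ValueError(f"event must be 'pre' or 'post', got {event!r}")
    return float(delta)


def expected_triplet_drift(r_pre: float, r_post: float,
                           config: TripletSTDPConfig = TripletSTDPConfig()) -> float:
    """Closed-form expected weight drift (per second) for independent
    Poisson pre/post trains under the all-to-all triplet rule.

    At a postsynaptic spike the mean fast presynaptic trace is r_pre*tau_2+
    and the mean slow postsynaptic trace (excluding the spike's own
    increment) is r_post*tau_y; symmetrically for depression.
    """
    if r_pre < 0 or r_post < 0:
        raise ValueError("rates must be nonnegative")
    c = config
    x = r_pre / 1000.0  # spikes per ms
    y = r_post / 1000.0
    per_ms = c.dw * x * y * (
        c.tau_2plus * (c.a2_plus + c.a3_plus * y * c.tau_y)
        - c.tau_2minus * (c.a2_minus + c.a3_minus * x * c.tau_x))
    return per_ms * 1000.0


def triplet_crossover_rate(config: TripletSTDPConfig = TripletSTDPConfig(),
                           lo: float = 1.0, hi: float = 100.0) -> float:
    """Matched pre/post rate (Hz) at which the expected drift changes sign."""
    return float(brentq(lambda r: expected_triplet_drift(r, r, config), lo, hi))


def simulate_triplet_drift(rate_pre: float, rate_post: float, duration_s: float,
                           rng: np.random.Generator,
                           config: TripletSTDPConfig = TripletSTDPConfig()) -> float:
    """Monte-Carlo drift (weight change per second) of one synapse driven by
    independent Poisson trains; the brute-force counterpart of
    ``expected_triplet_drift``."""
    t_ms = duration_s * 1000.0
    n_pre = rng.poisson(rate_pre / 1000.0 * t_ms)
    n_post = rng.poisson(rate_post / 1000.0 * t_ms)
    times = np.concatenate([rng.uniform(0, t_ms, n_pre), rng.uniform(0, t_ms, n_post)])
    kinds = np.concatenate([np.zeros(n_pre, dtype=int), np.ones(n_post, dtype=int)])
    order = np.argsort(times, kind="stable")
    traces = TripletTraces(config)
    dw = 0.0
    for t, k in zip(times[order], kinds[order]):
        dw += triplet_update_on_spike("post" if k else "pre", t, traces, config)
    return dw / duration_s


# ---------------------------------------------------------------------------
# LTPi

def ltpi_update(inh_spike_time: float, post_excitatory_spike_times,
                post_voltage_at_spike: float,
                config: LTPiConfig = LTPiConfig()) -> float:
    """Weight change of one I->E synapse for one inhibitory spike.

    +idW iff no postsynaptic excitatory spike falls within the +/-20 ms veto
    window and the postsynaptic voltage at the inhibitory spike time is
    above the depolarization threshold; otherwise 0.  Never negative.
    """
    ts = np.asarray(post_excitatory_spike_times, dtype=float)
    if ts.size and np.min(np.abs(ts - inh_spike_time)) <= config.veto_window:
        return 0.0
    thr = config.depolarization_threshold
    if thr is not None and post_voltage_at_spike <= thr:
        return 0.0
    return config.idw


# ---------------------------------------------------------------------------
# homeostasis and bounds

def homeostasis_step(weights: np.ndarray, mean_rate, goal_rate, epsilon: float,
                     synapse_class: str) -> np.ndarray:
    """Multiplicative postsynaptic scaling of all synapses onto each cell.

    ``weights`` has shape (n_pre, n_post); ``mean_rate`` and ``goal_rate``
    are per-post-cell (scalars broadcast).  Excitatory synapses scale by
    1 + eps*(goal - rate); inhibitory synapses onto excitatory cells scale
    by 1 + eps*(rate - goal): both push the rate toward the goal.
    """
    rate = np.broadcast_to(np.asarray(mean_rate, dtype=float), (weights.shape[1],))
    goal = np.broadcast_to(np.asarray(goal_rate, dtype=float), (weights.shape[1],))
    if synapse_class == "excitatory":
        factor = 1.0 + epsilon * (goal - rate)
    elif synapse_class == "inhibitory_to_e":
        factor = 1.0 + epsilon * (rate - goal)
    else:
        raise ValueError(f"unknown synapse_class {synapse_class!r}")
    return np.maximum(weights * factor[None, :], 0.0)


def enforce_bounds(weights: np.ndarray, trial_start_weights: np.ndarray,
                   upper_bound: float) -> np.ndarray:
    """Clamp to the 50%-per-trial cap and the global [0, 20 W0] bounds."""
    if weights.shape != trial_start_weights.shape:
        raise ValueError("shape mismatch between weights and trial-start weights")
    lo = np.maximum(0.0, 0.5 * trial_start_weights)
    hi = np.minimum(upper_bound, 1.5 * trial_start_weights)
    return np.clip(weights, lo, hi)


# ---------------------------------------------------------------------------
# online engines plugged into dynamics.run_trial

class _Caps:
    """Per-trial clamp bounds for one weight block."""

    def __init__(self, block):
        start = block.weights
        self.lo = np.maximum(0.0, 0.5 * start)
        self.hi = np.minimum(block.upper_bound, 1.5 * start)


class PairSTDPEngine:
    """All-to-all additive pair STDP on E->E and input->E synapses,
    implemented with exponential pre/post traces updated lazily at spike
    events."""

    def __init__(self, config: PairSTDPConfig = None):
        self.cfg = config or PairSTDPConfig()

    def begin_trial(self, network):
        nb = network.blocks
        self.W_ee = nb["ee"].weights
        self.M_ee = nb["ee"].mask.adjacency
        self.W_in = nb["in_e"].weights
        self.M_in = nb["in_e"].mask.adjacency
        self.caps_ee = _Caps(nb["ee"])
        self.caps_in = _Caps(nb["in_e"])
        n_e = self.W_ee.shape[0]
        n_g = self.W_in.shape[0]
        self.x_e = np.zeros(n_e)  # presynaptic traces, tau_plus
        self.y_e = np.zeros(n_e)  # postsynaptic traces, tau_minus
        self.x_in = np.zeros(n_g)
        self.t = 0.0

    def _decay(self, t):
        dt = t - self.t
        if dt > 0:
            fp = np.exp(-dt / self.cfg.tau_plus)
            fm = np.exp(-dt / self.cfg.tau_minus)
            self.x_e *= fp
            self.x_in *= fp
            self.y_e *= fm
            self.t = t

    def on_step(self, t, e_spk, i_spk, in_groups, in_counts, v_e):
        self._decay(t)
        cfg = self.cfg
        if e_spk.size:
            # depression: these cells as presynaptic against the post trace
            dep = cfg.dw * cfg.a_minus * self.y_e
            rows = self.W_ee[e_spk] - dep[None, :] * self.M_ee[e_spk]
            self.W_ee[e_spk] = np.clip(rows, self.caps_ee.lo[e_spk],
                                       self.caps_ee.hi[e_spk])
            # potentiation: these cells as postsynaptic against pre traces
            cols = (self.W_ee[:, e_spk]
                    + cfg.dw * cfg.a_plus * self.x_e[:, None] * self.M_ee[:, e_spk])
            self.W_ee[:, e_spk] = np.clip(cols, self.caps_ee.lo[:, e_spk],
                                          self.caps_ee.hi[:, e_spk])
            cols_in = (self.W_in[:, e_spk]
                       + cfg.dw * cfg.a_plus * self.x_in[:, None] * self.M_in[:, e_spk])
            self.W_in[:, e_spk] = np.clip(cols_in, self.caps_in.lo[:, e_spk],
                                          self.caps_in.hi[:, e_spk])
        if in_groups is not None:
            dep = cfg.dw * cfg.a_minus * self.y_e
            rows = (self.W_in[in_groups]
                    - in_counts[:, None] * dep[None, :] * self.M_in[in_groups])
            self.W_in[in_groups] = np.clip(rows, self.caps_in.lo[in_groups],
                                           self.caps_in.hi[in_groups])
        # trace increments after the all-to-all updates
        if e_spk.size:
            self.x_e[e_spk] += 1.0
            self.y_e[e_spk] += 1.0
        if in_groups is not None:
            self.x_in[in_groups] += in_counts

    def end_trial(self, result):
        pass


class TripletSTDPEngine:
    """Pfister-Gerstner triplet rule on E->E and input->E synapses."""

    def __init__(self, config: TripletSTDPConfig = None):
        self.cfg = config or TripletSTDPConfig()

    def begin_trial(self, network):
        nb = network.blocks
        self.W_ee = nb["ee"].weights
        self.M_ee = nb["ee"].mask.adjacency
        self.W_in = nb["in_e"].weights
        self.M_in = nb["in_e"].mask.adjacency
        self.caps_ee = _Caps(nb["ee"])
        self.caps_in = _Caps(nb["in_e"])
        n_e = self.W_ee.shape[0]
        n_g = self.W_in.shape[0]
        self.r1_e = np.zeros(n_e)
        self.r2_e = np.zeros(n_e)
        self.r1_in = np.zeros(n_g)
        self.r2_in = np.zeros(n_g)
        self.o1 = np.zeros(n_e)
        self.o2 = np.zeros(n_e)
        self.t = 0.0

    def _decay(self, t):
        dt = t - self.t
        if dt > 0:
            c = self.cfg
            f_r1 = np.exp(-dt / c.tau_2plus)
            f_r2 = np.exp(-dt / c.tau_x)
            self.r1_e *= f_r1
            self.r1_in *= f_r1
            self.r2_e *= f_r2
            self.r2_in *= f_r2
            self.o1 *= np.exp(-dt / c.tau_2minus)
            self.o2 *= np.exp(-dt / c.tau_y)
            self.t = t

    def on_step(self, t, e_spk, i_spk, in_groups, in_counts, v_e):
        self._decay(t)
        c = self.cfg
        if e_spk.size:
            # depression: spiking E cells as presynaptic
            dep = c.dw * self.o1[None, :] * (
                c.a2_minus + c.a3_minus * self.r2_e[e_spk][:, None])
            rows = self.W_ee[e_spk] - dep * self.M_ee[e_spk]
            self.W_ee[e_spk] = np.clip(rows, self.caps_ee.lo[e_spk],
                                       self.caps_ee.hi[e_spk])
            # potentiation: spiking E cells as postsynaptic
            pot = c.dw * self.r1_e[:, None] * (
                c.a2_plus + c.a3_plus * self.o2[None, e_spk])
            cols = self.W_ee[:, e_spk] + pot * self.M_ee[:, e_spk]
            self.W_ee[:, e_spk] = np.clip(cols, self.caps_ee.lo[:, e_spk],
                                          self.caps_ee.hi[:, e_spk])
            pot_in = c.dw * self.r1_in[:, None] * (
                c.a2_plus + c.a3_plus * self.o2[None, e_spk])
            cols_in = self.W_in[:, e_spk] + pot_in * self.M_in[:, e_spk]
            self.W_in[:, e_spk] = np.clip(cols_in, self.caps_in.lo[:, e_spk],
                                          self.caps_in.hi[:, e_spk])
        if in_groups is not None:
            dep = (in_counts[:, None] * c.dw * self.o1[None, :]
                   * (c.a2_minus + c.a3_minus * self.r2_in[in_groups][:, None]))
            rows = self.W_in[in_groups] - dep * self.M_in[in_groups]
            self.W_in[in_groups] = np.clip(rows, self.caps_in.lo[in_groups],
                                           self.caps_in.hi[in_groups])
        if e_spk.size:
            self.r1_e[e_spk] += 1.0
            self.r2_e[e_spk] += 1.0
            self.o1[e_spk] += 1.0
            self.o2[e_spk] += 1.0
        if in_groups is not None:
            self.r1_in[in_groups] += in_counts
            self.r2_in[in_groups] += in_counts

    def end_trial(self, result):
        pass


class LTPiEngine:
    """LTPi on I->E synapses with spike veto and depolarization gating.

    Inhibitory spikes and postsynaptic voltage snapshots are collected
    during the cue; vetoes are resolved at trial end so that excitatory
    spikes occurring after an inhibitory spike (and spikes from the
    relaxation window at the cue edge) can veto it.
    """

    def __init__(self, config: LTPiConfig = None):
        self.cfg = config or LTPiConfig()

    def begin_trial(self, network):
        blk = network.blocks["ie"]
        self.W_ie = blk.weights
        self.M_ie = blk.mask.adjacency
        self.caps = _Caps(blk)
        self.events: list = []  # (t, inhibitory ids, voltage snapshot of E cells)

    def on_step(self, t, e_spk, i_spk, in_groups, in_counts, v_e):
        if i_spk.size:
            self.events.append((t, i_spk.copy(), v_e.copy()))

    def end_trial(self, result):
        if not self.events:
            return
        cfg = self.cfg
        n_e = self.W_ie.shape[1]
        ev_times = np.array([e[0] for e in self.events])
        # veto table: for each E cell, is any of its spikes within the
        # window of each inhibitory-spike event time
        veto = np.zeros((len(self.events), n_e), dtype=bool)
        ids_e, times_e = result.spikes_e.ids, result.spikes_e.times
        order = np.argsort(ids_e, kind="stable")
        ids_sorted, times_sorted = ids_e[order], times_e[order]
        starts = np.searchsorted(ids_sorted, np.arange(n_e))
        stops = np.searchsorted(ids_sorted, np.arange(n_e), side="right")
        for j in range(n_e):
            ts = times_sorted[starts[j]:stops[j]]
            if ts.size == 0:
                continue
            pos = np.searchsorted(ts, ev_times)
            left = np.where(pos > 0, ev_times - ts[np.maximum(pos - 1, 0)], np.inf)
            right = np.where(pos < ts.size,
                             ts[np.minimum(pos, ts.size - 1)] - ev_times, np.inf)
            veto[:, j] = np.minimum(left, right) <= cfg.veto_window
        delta = np.zeros_like(self.W_ie)
        thr = cfg.depolarization_threshold
        for k, (t, i_ids, v_snap) in enumerate(self.events):
            eligible = ~veto[k]
            if thr is not None:
                eligible &= v_snap > thr
            if eligible.any():
                cols = np.flatnonzero(eligible)
                delta[np.ix_(i_ids, cols)] += cfg.idw * self.M_ie[np.ix_(i_ids, cols)]
        np.clip(self.W_ie + delta, self.caps.lo, self.caps.hi, out=self.W_ie)


def make_engines(condition: str,
                 pair_cfg: PairSTDPConfig = None,
                 triplet_cfg: TripletSTDPConfig = None,
                 ltpi_cfg: LTPiConfig = None) -> list:
    """Engine set for a named plasticity condition."""
    sets = {
        "initial": [],
        "pair_stdp": [PairSTDPEngine(pair_cfg)],
        "triplet_stdp": [TripletSTDPEngine(triplet_cfg)],
        "ltpi": [LTPiEngine(ltpi_cfg)],
        "ltpi+pair_stdp": [LTPiEngine(ltpi_cfg), PairSTDPEngine(pair_cfg)],
        "ltpi+triplet_stdp": [LTPiEngine(ltpi_cfg), TripletSTDPEngine(triplet_cfg)],
    }
    if condition not in sets:
        raise ValueError(f"unknown condition {condition!r}; allowed: {sorted(sets)}")
    return sets[condition]
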