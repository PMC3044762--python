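"""Clock-driven integration of the associative layer.

Leaky integrate-and-fire neurons with conductance-based AMPA / NMDA /
GABA_A synapses, a spike-triggered refractory conductance in place of a
hard voltage reset, and a dynamic (adaptive) spike threshold bounded at
150 mV.  Two noise sources act during integration: additive Gaussian
voltage noise (associative layer) and a piecewise-constant uniform
synaptic conductance noise on the AMPA and GABA_A channels.

Numerics: conductances decay by exact exponential factors between spikes;
the voltage follows exponential-Euler updates of the conductance balance
(exact for piecewise-constant conductances), with Euler--Maruyama sqrt(dt)
scaling for the additive voltage noise.  A configurable hard-reset mode
restores the textbook LIF for validation against the closed-form
interspike interval.

Unit system: mV, ms, uS.  Synaptic weights are dimensionless; a weight is
converted to a conductance jump through per-receptor unit conductances
(uS per unit weight) that are part of the kinetics configuration.  Their
defaults are calibrated so the standard initial network (p = 1/3) sits in
the high-activity regime (tens of Hz) while the sparsest networks
(p = 1/20) are nearly silent -- the activity contrast the study's input
grid is built around.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import rng as _rng
from .network_builder import InputEnsemble, NetworkInstance


@dataclass
class SynapseKinetics:
    """Receptor kinetics, refractory channel, and weight->conductance units."""

    e_ampa: float = 0.0  # mV
    tau_ampa: float = 2.0  # ms
    e_nmda: float = 0.0
    tau_nmda: float = 100.0
    e_gaba: float = -70.0
    tau_gaba: float = 10.0
    mg_concentration: float = 1.0  # mM, magnesium block
    nmda_slope_per_mv: float = 0.062
    nmda_scale: float = 3.57
    delta_g_ref: float = 0.002  # uS added per spike (before gain)
    refractory_gain: float = 1.0e6  # unit conversion: makes the channel repolarize
    v_ref: float = -70.0  # refractory reversal, mV
    threshold_jump: float = 2.0  # mV per spike
    threshold_tau: float = 50.0  # ms relaxation to base
    # unit conductances, uS per unit synaptic weight
    g_unit_ampa: float = 160.0
    g_unit_nmda: float = 8.0
    g_unit_gaba: float = 90.0


@dataclass
class NoiseConfig:
    """Amplitudes of the two noise sources (free parameters of the model,
    calibrated; see the methods note)."""

    voltage_noise_sd: float = 0.35  # mV per sqrt(ms), associative layer only
    conductance_amp_associative: float = 1.2  # uS, uniform [0, amp]
    conductance_amp_decision: float = 25.0
    refresh_ms: float = 5.0  # noise conductances held piecewise-constant
    voltage_noise_on: bool = True
    conductance_noise_on: bool = True


@dataclass
class IntegrationConfig:
    dt: float = 0.02  # ms
    cue_ms: float = 1000.0
    relax_ms: float = 500.0  # inputs-off relaxation before each cue
    hard_reset: bool = False  # validation mode: classic LIF reset, no g_ref

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class SpikeRecord:
    """Ordered spike events of one population over one trial."""

    ids: np.ndarray  # int neuron (or input-group) indices
    times: np.ndarray  # ms, nondecreasing
    population: str
    duration: float
    trial: int = 0

    def counts(self, n: int, t_start: float = 0.0,
               t_stop: Optional[float] = None) -> np.ndarray:
        t_stop = self.duration if t_stop is None else t_stop
        sel = (self.times >= t_start) & (self.times < t_stop)
        return np.bincount(self.ids[sel], minlength=n)

    def times_of(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]


@dataclass
class LayerState:
    """Carry-over dynamical state of one layer between trials."""

    v: np.ndarray
    g_ampa: np.ndarray
    g_nmda: np.ndarray
    g_gaba: np.ndarray
    g_ref: np.ndarray
    v_th: np.ndarray


@dataclass
class TrialResult:
    spikes_e: SpikeRecord
    spikes_i: SpikeRecord
    rates_e: np.ndarray  # Hz over the cue window
    rates_i: np.ndarray
    state: LayerState
    input_spikes: "SpikeRecord"
    voltage_trace: Optional[np.ndarray] = None  # (n_steps, n_recorded)


def nmda_gating(v, kinetics: SynapseKinetics = SynapseKinetics()):
    """Voltage-dependent magnesium unblock of the NMDA conductance,
    1 / (1 + [Mg] exp(-0.062 V) / 3.57); monotone in V, -> 1 as V -> +inf."""
    return 1.0 / (1.0 + kinetics.mg_concentration
                  * np.exp(-kinetics.nmda_slope_per_mv * np.asarray(v, dtype=float))
                  / kinetics.nmda_scale)


def generate_poisson_inputs(ensemble: InputEnsemble, stimulus_pair,
                            duration: float, seed_or_rng) -> SpikeRecord:
    """Independent homogeneous Poisson trains for the two active stimuli.

    Each of the 2G active groups fires at 480/G Hz for ``duration`` ms;
    groups of the inactive stimuli are silent.
    """
    gen = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    active = np.flatnonzero(ensemble.active_groups(stimulus_pair))
    rate_ms = ensemble.rate_per_group / 1000.0
    ids, times = [], []
    for g in active:
        k = gen.poisson(rate_ms * duration)
        ts = np.sort(gen.uniform(0.0, duration, size=k))
        ids.append(np.full(k, g, dtype=np.int64))
        times.append(ts)
    ids = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    times = np.concatenate(times) if times else np.empty(0)
    order = np.argsort(times, kind="stable")
    return SpikeRecord(ids[order], times[order], "input", duration)


def _initial_state(v_l, v_th_base) -> LayerState:
    n = v_l.size
    return LayerState(v=v_l.copy(), g_ampa=np.zeros(n), g_nmda=np.zeros(n),
                      g_gaba=np.zeros(n), g_ref=np.zeros(n),
                      v_th=v_th_base.copy())


def run_trial(network: NetworkInstance, input_spikes: SpikeRecord,
              engines: Sequence = (),
              integ: IntegrationConfig = None,
              kinetics: SynapseKinetics = None,
              noise: NoiseConfig = None,
              noise_rng: Optional[np.random.Generator] = None,
              state: Optional[LayerState] = None,
              record_voltage_of: Optional[Sequence[int]] = None,
              trial: int = 0) -> TrialResult:
    """Simulate one trial: ``relax_ms`` of inputs-off relaxation followed by
    a 1 s cue during which the input ensemble drives the layer.

    Plasticity ``engines`` receive every spike event during the cue and may
    update the network's weight blocks in place (bounds are their
    responsibility; see ``plasticity``).  Cue-window firing rates are
    returned per neuron.  Passing the returned ``state`` back in carries
    membrane and synaptic state across consecutive trials.
    """
    integ = integ or IntegrationConfig()
    kin = kinetics or SynapseKinetics()
    noise = noise or NoiseConfig()
    gen = noise_rng if noise_rng is not None else _rng.child_rng(
        network.config.master_seed, _rng.NOISE, trial)

    cfg = network.config
    n_e, n_i = cfg.n_excitatory, cfg.n_inhibitory
    n = n_e + n_i
    pe, pi = network.params_e, network.params_i

    v_l = np.concatenate([pe["leak_reversal"], pi["leak_reversal"]])
    g_l = np.concatenate([pe["leak_conductance"], pi["leak_conductance"]])
    tau_m = np.concatenate([pe["membrane_time_constant"], pi["membrane_time_constant"]])
    cap = g_l * tau_m
    v_th_base = np.concatenate([pe["threshold_base"], pi["threshold_base"]])
    v_reset = np.concatenate([pe["reset_voltage"], pi["reset_voltage"]])
    v_th_max = np.concatenate([pe["threshold_max"], pi["threshold_max"]])
    tau_reset = np.concatenate([pe["refractory_time_constant"],
                                pi["refractory_time_constant"]])

    dt = integ.dt
    dec_a = np.exp(-dt / kin.tau_ampa)
    dec_n = np.exp(-dt / kin.tau_nmda)
    dec_g = np.exp(-dt / kin.tau_gaba)
    dec_r = np.exp(-dt / np.asarray(tau_reset, dtype=float))
    dec_th = np.exp(-dt / kin.threshold_tau)
    gref_jump = 0.0 if integ.hard_reset else kin.delta_g_ref * kin.refractory_gain

    v_l = np.asarray(v_l, dtype=float)
    g_l = np.asarray(g_l, dtype=float)
    cap = np.asarray(cap, dtype=float)
    v_th_base = np.asarray(v_th_base, dtype=float)
    v_reset = np.asarray(v_reset, dtype=float)
    v_th_max = np.asarray(v_th_max, dtype=float)
    dec_r = np.asarray(dec_r, dtype=float)

    st = state if state is not None else _initial_state(v_l, v_th_base)
    v, gA, gN, gG, gR, vth = st.v, st.g_ampa, st.g_nmda, st.g_gaba, st.g_ref, st.v_th

    W_ee = network.blocks["ee"].weights
    W_ie = network.blocks["ie"].weights
    W_ii = network.blocks["ii"].weights
    W_ei = network.blocks["ei"].weights if "ei" in network.blocks else None
    W_in_e = network.blocks["in_e"].weights
    W_in_i = network.blocks["in_i"].weights

    kA, kN, kG = kin.g_unit_ampa, kin.g_unit_nmda, kin.g_unit_gaba
    sig_v = noise.voltage_noise_sd if noise.voltage_noise_on else 0.0
    amp_g = noise.conductance_amp_associative if noise.conductance_noise_on else 0.0
    sqdt = np.sqrt(dt)
    noise_refresh = max(1, int(round(noise.refresh_ms / dt)))
    g_exc_noise = np.zeros(n)
    g_inh_noise = np.zeros(n)

    total_ms = integ.relax_ms + integ.cue_ms
    n_steps = int(round(total_ms / dt))
    cue_start_step = int(round(integ.relax_ms / dt))

    # pre-bin input events by step (offset into the cue window)
    in_steps = cue_start_step + np.floor(input_spikes.times / dt).astype(np.int64)
    in_ids = input_spikes.ids
    in_ptr = 0
    n_in_events = in_steps.size

    for eng in engines:
        eng.begin_trial(network)

    rec_steps_e: list = []
    rec_ids_e: list = []
    rec_steps_i: list = []
    rec_ids_i: list = []
    cue_count_e = np.zeros(n_e, dtype=np.int64)
    cue_count_i = np.zeros(n_i, dtype=np.int64)

    rec_v = None
    if record_voltage_of is not None:
        rec_idx = np.asarray(record_voltage_of, dtype=np.int64)
        rec_v = np.empty((n_steps, rec_idx.size))

    e_spk = np.empty(0, dtype=np.int64)
    i_spk = np.empty(0, dtype=np.int64)

    for step in range(n_steps):
        t = step * dt
        in_cue = step >= cue_start_step

        gA *= dec_a
        gN *= dec_n
        gG *= dec_g
        gR *= dec_r

        # recurrent delivery of last step's spikes
        if e_spk.size:
            drive = W_ee[e_spk].sum(axis=0)
            gA[:n_e] += kA * drive
            gN[:n_e] += kN * drive
            if W_ei is not None:
                d2 = W_ei[e_spk].sum(axis=0)
                gA[n_e:] += kA * d2
                gN[n_e:] += kN * d2
        if i_spk.size:
            gG[:n_e] += kG * W_ie[i_spk].sum(axis=0)
            gG[n_e:] += kG * W_ii[i_spk].sum(axis=0)

        # external input delivery
        ev_groups = ev_counts = None
        if in_cue and in_ptr < n_in_events and in_steps[in_ptr] <= step:
            j = in_ptr
            while j < n_in_events and in_steps[j] == step:
                j += 1
            ev_groups, ev_counts = np.unique(in_ids[in_ptr:j], return_counts=True)
            in_ptr = j
            drive_e = ev_counts @ W_in_e[ev_groups]
            drive_i = ev_counts @ W_in_i[ev_groups]
            gA[:n_e] += kA * drive_e
            gN[:n_e] += kN * drive_e
            gA[n_e:] += kA * drive_i
            gN[n_e:] += kN * drive_i

        # conductance balance; exponential-Euler voltage update
        b = 1.0 / (1.0 + kin.mg_concentration
                   * np.exp(-kin.nmda_slope_per_mv * v) / kin.nmda_scale)
        if amp_g > 0 and step % noise_refresh == 0:
            g_exc_noise = amp_g * gen.random(n)
            g_inh_noise = amp_g * gen.random(n)
        g_ampa_t = gA + g_exc_noise
        g_gaba_t = gG + g_inh_noise
        g_nmda_t = gN * b
        g_tot = g_l + g_ampa_t + g_nmda_t + g_gaba_t + gR
        v_inf = (g_l * v_l + g_ampa_t * kin.e_ampa + g_nmda_t * kin.e_nmda
                 + g_gaba_t * kin.e_gaba + gR * kin.v_ref) / g_tot
        v += (v_inf - v) * (1.0 - np.exp(-dt * g_tot / cap))
        if sig_v > 0:
            v += sig_v * sqdt * gen.standard_normal(n)

        spiked = v >= vth
        if spiked.any():
            idx = np.flatnonzero(spiked)
            if integ.hard_reset:
                v[idx] = v_reset[idx]
            else:
                gR[idx] += gref_jump
            vth[idx] = np.minimum(vth[idx] + kin.threshold_jump, v_th_max[idx])
            e_spk = idx[idx < n_e]
            i_spk = idx[idx >= n_e] - n_e
            if e_spk.size:
                rec_steps_e.append(np.full(e_spk.size, t))
                rec_ids_e.append(e_spk)
            if i_spk.size:
                rec_steps_i.append(np.full(i_spk.size, t))
                rec_ids_i.append(i_spk)
            if in_cue:
                cue_count_e += np.bincount(e_spk, minlength=n_e)
                cue_count_i += np.bincount(i_spk, minlength=n_i)
        else:
            e_spk = i_spk = np.empty(0, dtype=np.int64)

        vth = v_th_base + (vth - v_th_base) * dec_th

        if in_cue and engines and (e_spk.size or i_spk.size or ev_groups is not None):
            for eng in engines:
                eng.on_step(t, e_spk, i_spk, ev_groups, ev_counts, v[:n_e])

        if rec_v is not None:
            rec_v[step] = v[rec_idx]

    st.v, st.g_ampa, st.g_nmda, st.g_gaba, st.g_ref, st.v_th = v, gA, gN, gG, gR, vth

    def _pack(steps, ids, pop, n_pop):
        times = np.concatenate(steps) if steps else np.empty(0)
        nid = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
        return SpikeRecord(nid, times, pop, total_ms, trial)

    spikes_e = _pack(rec_steps_e, rec_ids_e, "associative_E", n_e)
    spikes_i = _pack(rec_steps_i, rec_ids_i, "associative_I", n_i)
    rates_e = cue_count_e / (integ.cue_ms / 1000.0)
    rates_i = cue_count_i / (integ.cue_ms / 1000.0)

    result = TrialResult(spikes_e, spikes_i, rates_e, rates_i, st,
                         input_spikes, rec_v)
    for eng in engines:
        eng.end_trial(result)
    return result
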