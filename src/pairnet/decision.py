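"""Winner-take-all decision circuit and reward learning.

Two pools (Release, Hold) of 200 excitatory + 50 inhibitory cells compete
through all-to-all within-pool excitation and direct cross-inhibition.
A linearly ramping urgency conductance (0 at cue onset, 5 uS at cue end)
drives both excitatory pools so a decision is made every trial even
without afferent drive.  The winner is read out as the pool with the
higher mean excitatory rate over the final 100 ms of the cue.

Afferents from the associative excitatory cells are trained by a
dopamine-modulated Hebbian rule: on a rewarded (correct) trial, synapses
from coactive associative cells onto the winning pool strengthen; on an
unrewarded trial the dopamine dip weakens them.  Losing-pool afferents
are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import rng as _rng
from .dynamics import (IntegrationConfig, NoiseConfig, SpikeRecord,
                       SynapseKinetics)
from .network_builder import DecisionInstance

POOL_NAMES = ("Release", "Hold")


@dataclass
class UrgencyConfig:
    g_max: float = 5.0  # uS at cue end


def decision_kinetics() -> SynapseKinetics:
    """Receptor kinetics for the decision layer.

    Same receptors and time constants as the associative layer; the unit
    conductances are calibrated separately because the decision pools rely
    on NMDA-dominated self-excitation for bistable persistence and on
    strong GABA_A cross-inhibition for winner-take-all exclusivity.
    """
    return SynapseKinetics(g_unit_ampa=1.0, g_unit_nmda=1.0, g_unit_gaba=3.0)


@dataclass
class RewardRuleConfig:
    eta: float = 1e-4  # learning rate per trial, scaled by presynaptic rate
    coactivity_threshold: float = 1.0  # Hz floor defining "coactive"
    rate_proportional: bool = True  # False: binary Hebbian eligibility


@dataclass
class DecisionOutcome:
    winner: str  # Release | Hold
    pool_rates: np.ndarray  # mean E rate per pool over the readout window, Hz
    anomalous: bool  # both pools persistently co-active
    correct: Optional[bool] = None
    reward: Optional[int] = None  # +1 reward, -1 dopamine dip
    spikes_e: Optional[SpikeRecord] = None
    spikes_i: Optional[SpikeRecord] = None


def urgency_conductance(t: float, cue_start: float, cue_end: float,
                        config: UrgencyConfig = UrgencyConfig()) -> float:
    """Urgency ramp: 0 before the cue, linear to g_max at cue end."""
    if t < cue_start:
        return 0.0
    if t >= cue_end:
        return config.g_max
    return config.g_max * (t - cue_start) / (cue_end - cue_start)


def run_decision(decision: DecisionInstance, assoc_spikes: SpikeRecord,
                 cue_start: float, cue_end: float,
                 noise_rng: np.random.Generator,
                 kinetics: SynapseKinetics = None,
                 noise: NoiseConfig = None,
                 urgency: UrgencyConfig = UrgencyConfig(),
                 dt: float = 0.05,
                 readout_ms: float = 100.0,
                 anomaly_ratio: float = 2.0) -> DecisionOutcome:
    """Simulate the decision layer over the cue window of one trial.

    ``assoc_spikes`` is the associative excitatory spike record of the same
    trial (times in the trial frame); its spikes drive the afferent block.
    The decision layer receives conductance noise only.
    """
    kin = kinetics or decision_kinetics()
    noise = noise or NoiseConfig()

    pe, pi = decision.params_e, decision.params_i
    n_e, n_i = len(pe), len(pi)
    n = n_e + n_i
    v_l = np.concatenate([pe["leak_reversal"], pi["leak_reversal"]]).astype(float)
    g_l = np.concatenate([pe["leak_conductance"], pi["leak_conductance"]]).astype(float)
    tau_m = np.concatenate([pe["membrane_time_constant"],
                            pi["membrane_time_constant"]]).astype(float)
    cap = g_l * tau_m
    v_th_base = np.concatenate([pe["threshold_base"], pi["threshold_base"]]).astype(float)
    v_th_max = np.concatenate([pe["threshold_max"], pi["threshold_max"]]).astype(float)
    tau_reset = np.concatenate([pe["refractory_time_constant"],
                                pi["refractory_time_constant"]]).astype(float)

    W_ee = decision.blocks["ee_pool"].weights
    W_ei = decision.blocks["ei_pool"].weights
    W_ie = decision.blocks["ie_cross"].weights
    W_aff = decision.afferent.weights

    dec_a = np.exp(-dt / kin.tau_ampa)
    dec_n = np.exp(-dt / kin.tau_nmda)
    dec_g = np.exp(-dt / kin.tau_gaba)
    dec_r = np.exp(-dt / tau_reset)
    dec_th = np.exp(-dt / kin.threshold_tau)
    gref_jump = kin.delta_g_ref * kin.refractory_gain
    kA, kN, kG = kin.g_unit_ampa, kin.g_unit_nmda, kin.g_unit_gaba
    amp_g = noise.conductance_amp_decision if noise.conductance_noise_on else 0.0
    noise_refresh = max(1, int(round(noise.refresh_ms / dt)))
    g_exc_n = np.zeros(n)
    g_inh_n = np.zeros(n)

    v = v_l.copy()
    gA = np.zeros(n)
    gN = np.zeros(n)
    gG = np.zeros(n)
    gR = np.zeros(n)
    vth = v_th_base.copy()

    # afferent events binned by step over the cue window
    sel = (assoc_spikes.times >= cue_start) & (assoc_spikes.times < cue_end)
    aff_steps = np.floor((assoc_spikes.times[sel] - cue_start) / dt).astype(np.int64)
    aff_ids = assoc_spikes.ids[sel]
    order = np.argsort(aff_steps, kind="stable")
    aff_steps, aff_ids = aff_steps[order], aff_ids[order]
    ptr, n_events = 0, aff_steps.size

    n_steps = int(round((cue_end - cue_start) / dt))
    readout_step = n_steps - int(round(readout_ms / dt))
    count_e = np.zeros(n_e, dtype=np.int64)
    rec_ids_e, rec_times_e = [], []
    rec_ids_i, rec_times_i = [], []

    e_spk = np.empty(0, dtype=np.int64)
    i_spk = np.empty(0, dtype=np.int64)

    for step in range(n_steps):
        t = cue_start + step * dt
        gA *= dec_a
        gN *= dec_n
        gG *= dec_g
        gR *= dec_r

        if e_spk.size:
            drive_e = W_ee[e_spk].sum(axis=0)
            drive_i = W_ei[e_spk].sum(axis=0)
            gA[:n_e] += kA * drive_e
            gN[:n_e] += kN * drive_e
            gA[n_e:] += kA * drive_i
            gN[n_e:] += kN * drive_i
        if i_spk.size:
            gG[:n_e] += kG * W_ie[i_spk].sum(axis=0)

        if ptr < n_events and aff_steps[ptr] <= step:
            j = ptr
            while j < n_events and aff_steps[j] == step:
                j += 1
            drive = W_aff[aff_ids[ptr:j]].sum(axis=0)
            ptr = j
            gA[:n_e] += kA * drive
            gN[:n_e] += kN * drive

        g_urg = urgency_conductance(t, cue_start, cue_end, urgency)
        b = 1.0 / (1.0 + kin.mg_concentration
                   * np.exp(-kin.nmda_slope_per_mv * v) / kin.nmda_scale)
        if amp_g > 0 and step % noise_refresh == 0:
            g_exc_n = amp_g * noise_rng.random(n)
            g_inh_n = amp_g * noise_rng.random(n)
        g_ampa_t = gA + g_exc_n
        g_ampa_t[:n_e] = g_ampa_t[:n_e] + g_urg
        g_gaba_t = gG + g_inh_n
        g_nmda_t = gN * b
        g_tot = g_l + g_ampa_t + g_nmda_t + g_gaba_t + gR
        v_inf = (g_l * v_l + g_ampa_t * kin.e_ampa + g_nmda_t * kin.e_nmda
                 + g_gaba_t * kin.e_gaba + gR * kin.v_ref) / g_tot
        v += (v_inf - v) * (1.0 - np.exp(-dt * g_tot / cap))

        spiked = v >= vth
        if spiked.any():
            idx = np.flatnonzero(spiked)
            gR[idx] += gref_jump
            vth[idx] = np.minimum(vth[idx] + kin.threshold_jump, v_th_max[idx])
            e_spk = idx[idx < n_e]
            i_spk = idx[idx >= n_e] - n_e
            if e_spk.size:
                rec_ids_e.append(e_spk)
                rec_times_e.append(np.full(e_spk.size, t))
                if step >= readout_step:
                    count_e += np.bincount(e_spk, minlength=n_e)
            if i_spk.size:
                rec_ids_i.append(i_spk)
                rec_times_i.append(np.full(i_spk.size, t))
        else:
            e_spk = i_spk = np.empty(0, dtype=np.int64)
        vth = v_th_base + (vth - v_th_base) * dec_th

    rates = count_e / (readout_ms / 1000.0)
    pool_rates = np.array([rates[decision.pool_of_e == 0].mean(),
                           rates[decision.pool_of_e == 1].mean()])
    if pool_rates[0] == pool_rates[1]:
        winner_idx = int(noise_rng.integers(2))
    else:
        winner_idx = int(np.argmax(pool_rates))
    lo, hi = np.sort(pool_rates)
    anomalous = bool(hi > 0 and lo > 0 and hi < anomaly_ratio * lo)

    def _pack(ids, times, pop):
        nid = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
        ts = np.concatenate(times) if times else np.empty(0)
        return SpikeRecord(nid, ts, pop, cue_end, assoc_spikes.trial)

    return DecisionOutcome(POOL_NAMES[winner_idx], pool_rates, anomalous,
                           spikes_e=_pack(rec_ids_e, rec_times_e, "decision_E"),
                           spikes_i=_pack(rec_ids_i, rec_times_i, "decision_I"))


def da_reward_update(decision: DecisionInstance, assoc_cue_rates: np.ndarray,
                     outcome: DecisionOutcome,
                     config: RewardRuleConfig = RewardRuleConfig()) -> None:
    """Dopamine-modulated Hebbian update of the associative->decision
    afferents, in place.

    DA = +1 on a correct (rewarded) trial, -1 on the dopamine dip of an
    incorrect one.  Only afferents from coactive associative cells (cue
    rate above the coactivity floor) onto the winning pool change:
    dW = eta * DA * activity.  Like every connection, afferents obey the
    50%-per-trial change cap and the global [0, 20 DW0] bounds.
    """
    if outcome.correct is None:
        raise ValueError("outcome must be resolved (correct set) before reward")
    da = 1 if outcome.correct else -1
    outcome.reward = da
    act = np.asarray(assoc_cue_rates, dtype=float).copy()
    act[act < config.coactivity_threshold] = 0.0
    if not config.rate_proportional:
        act = (act > 0).astype(float)
    cols = np.flatnonzero(decision.pool_of_e == POOL_NAMES.index(outcome.winner))
    W = decision.afferent.weights
    start = W[:, cols]
    proposed = start + config.eta * da * act[:, None]
    lo = np.maximum(0.0, 0.5 * start)
    hi = np.minimum(decision.afferent.upper_bound, 1.5 * start)
    W[:, cols] = np.clip(proposed, lo, hi)
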