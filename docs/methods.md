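# Methods

## Model overview

`pairnet` simulates a two-layer spiking model of biconditional (XOR)
discrimination. Four stimuli A, B, C, D are presented in pairs; A+B and
C+D demand one response ("Release"), A+D and C+B the other ("Hold"), so
no cell tuned to a single stimulus can solve the task. An **associative
layer** of 400 leaky integrate-and-fire neurons (320 excitatory, 80
inhibitory) receives the stimuli through Poisson input groups and is
reshaped by synaptic plasticity; a **decision layer** of two
winner-take-all pools (200 E + 50 I each) reads the associative
excitatory cells out through all-to-all afferents trained by a
dopamine-modulated reward rule.

## Neurons and synapses

Membrane dynamics (units mV, ms, µS; capacitance C = g_L·τ_m):

    C dV/dt = g_L(V_L − V) + g_AMPA(E_AMPA − V) + B(V)·g_NMDA(E_NMDA − V)
              + g_GABA(E_GABA − V) + g_ref(V_ref − V) + noise

with E_AMPA = E_NMDA = 0 mV, E_GABA = −70 mV, decay constants
τ_AMPA = 2 ms, τ_NMDA = 100 ms, τ_GABA = 10 ms, and the magnesium block

    B(V) = 1 / (1 + [Mg]·exp(−0.062·V)/3.57),   [Mg] = 1 mM.

Conductances jump on presynaptic spikes and decay exponentially. There is
**no hard voltage reset**: each spike increments a refractory conductance
(δ_gref = 0.002 per spike, reversal −70 mV) that repolarizes the cell
with the per-cell refractory time constant (2 ms excitatory, 1 ms
inhibitory), and increments a **dynamic threshold** (+2 mV per spike,
relaxing to base with τ = 50 ms, hard ceiling 150 mV) that allows
decision-layer cells to sustain persistent firing without bursting. A
configurable hard-reset mode restores the textbook LIF for validation
against the closed-form interspike interval.

Associative-layer cell parameters are heterogeneous, drawn uniformly
about their means: V_L = −70 ± 2.5 mV, τ_m = 10 ± 0.75 ms,
g_L = 35 ± 1 µS (40 or 50 µS in the high-threshold regimes),
V_th = −50 ± 2 mV, τ_reset = 2 ± 0.25 ms (E) / 1 ± 0.25 ms (I).
Decision-layer cells are homogeneous (E: τ_m = 20 ms, V_th = −48 mV;
I: τ_m = 10 ms, g_L = 30 µS, V_th = −50 mV).

### Unit conductances (closing the unit system)

The conventional parameter set above is internally inconsistent as a
dynamical system: a leak of 35 µS cannot be repolarized by a 0.002 µS refractory
increment, and the synaptic weight scale W₀ = 0.05 is dimensionless.
We therefore convert weights (and the refractory increment) to
conductances through per-receptor **unit conductances**, free parameters
calibrated once against the model's target activity regimes and then
frozen:

| parameter | associative | decision | role |
|---|---|---|---|
| g_unit_AMPA | 160 | 1 | µS per unit weight |
| g_unit_NMDA | 8 | 1 | µS per unit weight |
| g_unit_GABA | 90 | 3 | µS per unit weight |
| refractory gain | 10⁶ | 10⁶ | makes δ_gref repolarize |

The associative calibration targets the initial-activity contrast the
input grid is designed around: dense-input networks (p = 1/2 … 1/5) fire at tens of Hz while
the sparsest networks (p = 1/10, 1/20) are nearly silent, and the
trained LTPi equilibrium keeps I→E weights interior to their bounds
(excitatory rates settle at the 8 Hz homeostatic goal). The decision
calibration targets functional winner-take-all behaviour: exactly one
pool active per trial, ~50/50 outcomes under symmetric drive, and
trainability to ceiling by the reward rule. `analysis/02` and the test
suite recompute these regimes from scratch.

### Noise

Two sources; the noise forms are part of the model while their
amplitudes are free parameters: additive Gaussian voltage noise
(0.35 mV·ms^−1/2, associative layer only) with Euler–Maruyama √dt
scaling, and uniform synaptic conductance noise on the AMPA and GABA_A
channels, drawn per neuron from [0, amp] (amp = 1.2 µS associative,
25 µS decision) and held piecewise-constant for 5 ms. The hold time
matters: per-step white draws average out on the membrane and cannot
ignite the decision pools; 5 ms draws give the noise membrane-timescale
power, acting as the background drive that attractor decision circuits
of this family require.

## Connectivity and the network grid

Associative layer: E→E sparse-random at 10%; I→E at 25%; I→I all-to-all;
inhibition is feedforward (no E→I) except in the recurrent-inhibition
regime (E→I at 25%). Initial weights are uniform W₀ ± 50% with
W₀ = 0.05, scaled by 400/n so total recurrent drive is invariant under
network-size changes (input weights are not scaled). Each stimulus is
carried by G ∈ {2, 4, 6, 10, 20} independent Poisson groups firing at
480/G Hz, each projecting to every associative cell with probability
p ∈ {1/2, 1/3, 1/5, 1/10, 1/20}; the 5 × 5 product is the 25-network
grid over input sparseness × input correlation. Regime variants cover
high thresholds (g_L 40/50 µS), 4× initial inhibition, a 4 Hz
homeostatic goal, recurrent inhibition, and homogeneous
(inputs/E→E/I→E/cell-parameter) controls.

Decision layer: within-pool E→E and E→I all-to-all at W₀ = 0.25;
cross-inhibition direct from each pool's I cells to the opposing pool's
E cells; afferents from all associative E cells all-to-all at
DW₀ = 0.075 (0.125 for untrained sparse networks, p ≤ 1/10). A linear
urgency conductance ramps from 0 at cue onset to 5 µS at cue end on both
excitatory pools, guaranteeing a choice every trial. The winner is the
pool with the higher mean excitatory rate over the final 100 ms
(exact tie → uniform random).

## Plasticity rules

All rules respect a 50%-per-trial change cap relative to the trial-start
weight and global bounds [0, 20·W₀] (per-block W₀). Rules act during the
cue; homeostasis applies once per trial.

**Pair STDP** (E→E, input→E): all-to-all trace implementation of the
additive exponential window, ΔW = +dW·A⁺·e^(−Δt/τ⁺) for pre-before-post,
−dW·A⁻·e^(−|Δt|/τ⁻) otherwise, with A⁺ = 1.20, A⁻ = 0.80, τ⁺ = 16 ms,
τ⁻ = 25 ms, dW = 0.005. Simultaneous spikes contribute zero.

**Triplet STDP** (E→E, input→E): Pfister–Gerstner trace model with the
all-to-all cortical amplitude set (A₂⁺ = 5·10⁻¹⁰, A₂⁻ = 7·10⁻³,
A₃⁺ = 6.2·10⁻³, A₃⁻ = 2.3·10⁻⁴; τ₂⁺ = 16.68 ms, τ₂⁻ = 33.7 ms,
τ_y = 125 ms, τ_x = 101 ms), scaled by dW = 0.005. On a postsynaptic
spike the weight gains dW·r₁·(A₂⁺ + A₃⁺·o₂); on a presynaptic spike it
loses dW·o₁·(A₂⁻ + A₃⁻·r₂), traces taken just before their own
increment. For uncorrelated Poisson trains at matched rate r the
expected drift is

    dW·x·y·[τ₂⁺(A₂⁺ + A₃⁺·y·τ_y) − τ₂⁻(A₂⁻ + A₃⁻·x·τ_x)],  x = y = r,

whose sign changes at 19.4 Hz — the ~20 Hz LTD-to-LTP crossover. This
closed form serves as the independent oracle for the event-driven
implementation (they agree within sampling error across 5–40 Hz).

**LTPi** (I→E): each inhibitory spike potentiates the synapse by
idW = 0.005 unless vetoed by a postsynaptic excitatory spike within
±20 ms (spikes from the pre-cue relaxation window can veto cue-edge
events) or the postsynaptic voltage at the inhibitory spike time is at
or below the depolarization threshold (−65 mV default; sweepable, None
disables). LTPi never depresses; depression is left to homeostasis.

**Homeostasis**: multiplicative postsynaptic scaling once per trial from
cue-window mean rates. Excitatory synapses onto cell i scale by
1 + ε(r_goal,i − r_i), inhibitory ones by 1 + ε(r_i − r_goal,i), with
ε = 0.0001 (input→E, E→E) and ε = 0.01 (I→E); goals 8 Hz (4 Hz in the
low-goal regime) with a 5 Hz-wide uniform per-cell jitter, interpreted
as centered on the mean (±2.5 Hz). I→I synapses are static; the
inhibitory goal rate is kept as a diagnostic only.

**Reward rule** (associative→decision afferents): after each trial,
DA = +1 if the choice was correct, −1 otherwise, and afferents from
coactive cells (cue rate ≥ 1 Hz) onto the *winning* pool change by
η·DA·rate (η = 10⁻⁴, rate-proportional eligibility; a binary variant
is configurable). η is set so that single-trial changes stay small
relative to DW₀ even at high presynaptic rates — larger values saturate
the 50%-per-trial cap every trial and collapse the afferents through a
multiplicative random walk. Losing-pool afferents are untouched; like
all connections, afferents obey the per-trial cap and clamp to
[0, 20·DW₀].

## Protocol

Trials are balanced pseudorandom blocks of four (one of each pair,
shuffled), preventing long single-pair runs from biasing homeostasis.
Each trial: 500 ms inputs-off relaxation (state carried across trials),
1 s cue, plasticity hooks during the cue, decision simulation over the
cue window, reward update, homeostasis, bound enforcement. Selectivity
is estimated from frozen-plasticity probe blocks (default 5 cues per
pair) before training and every 40 trials. In the "initial" condition
the associative layer is fully frozen (homeostasis off) while reward
plasticity still trains the decision afferents — that is how untrained
network performance is measured.

## Statistics

Per-cell stimulus-pair selectivity s = (max − mean)/mean over the four
pair rates, 0 for uniform responders, 3 for single-pair responders;
silent cells score 0. The network value averages all excitatory cells
(an active-only variant with a 0.5 Hz floor reproduces the
active-cells-only analysis). Decision performance is fraction correct in
40-trial bins, classified reliable ≥ 85%, borderline 76–84%, unreliable
≤ 75%. Cross-inhibition is quantified by grouping cells by preferred
pair (argmax of post-training probe rates, ties to the lowest index) and
averaging I→E weight changes between groups; cells below the 0.5 Hz
activity floor carry no meaningful preference and are excluded from
grouping. Performance–selectivity coupling uses the two-parameter
sigmoid y = 50 + 50/(1 + e^(−(x−x₀)/δ)) fit by nonlinear least squares.

## Numerics

Integration is clock-driven. Conductances decay by exact exponential
factors; the voltage uses an exponential-Euler update (exact for
piecewise-constant conductances and unconditionally stable under the
large refractory conductance), with additive voltage noise scaled by
√dt. dt defaults to 0.02 ms; desk-scale runs use 0.05 ms (0.1 ms in the
fastest tests), which changes noise-free spike counts by at most one
spike per neuron per trial. Spikes are delivered at the following step
(zero axonal delay). Every randomness source (structure, cell
parameters, weights, inputs, integration noise, trial order, decision
noise, reward) draws from a named child stream of one master seed, so
each stage is independently and bit-exactly reproducible.

## Desk scale versus full scale

The full study is 25 networks × 6 conditions × ≥ 4 instantiations ×
800 trials — cluster-scale. The analysis drivers and tests run the same
machinery at desk scale: 200-neuron networks, one standard grid cell
(6 groups, p = 1/3), 120–160 trials, probes of 2 cues per pair,
dt = 0.05 ms. At this scale LTPi already sparsifies activity to the
homeostatic goal, raises network-mean selectivity roughly twenty-fold,
and produces the off-diagonal > diagonal cross-inhibition signature;
the full grid remains available through `run_condition_grid` with
paper-scale arguments.

## What the generator does and does not emulate

The network builder *is* the study's data generator: all inputs are
synthetic by design (Poisson input groups, random connectivity,
uniform parameter heterogeneity). It reproduces the stated connectivity
statistics, heterogeneity ranges, input rates, and regime variants. It
does not model structured (small-world or motif-based) connectivity,
synapse creation or pruning, short-term plasticity, conduction delays,
or multi-compartment effects — so passing tests speak to the stated
model class, not to cortical tissue. Noise amplitudes, absolute conductance
scales and decision up-state rates are calibrated free parameters; results that
depend on their precise values (absolute firing rates, exact trained
weight magnitudes) should be read as regime-level, while structural
results (selectivity bounds, crossover rate, XOR mapping, cross-
inhibition sign, bound enforcement) are parameter-independent.

## Known limitations

* Decision-pool up-states run hotter (~100 Hz) than classic attractor
  implementations (~30–50 Hz); winner identity, not winner rate, is the
  quantity used downstream.
* The LTPi voltage gate samples the membrane at the inhibitory spike
  time only (no temporal averaging).
* Homeostasis uses a multiplicative form; other monotone updates that
  push rates toward the goal would serve equally.
* Desk-scale runs use one grid cell and few instantiations; grid-wide
  counts (e.g. how many of 25 networks become reliable) need the
  full-scale runner.
* Closed-loop reward learning is the slowest process in the model: with
  surrogate perfectly-selective afferents it reaches ceiling within ~120
  trials, but in the full loop the first ~80 trials predate selectivity
  emergence and the trained activity is sparse, so at desk scale
  (200 neurons, 400 trials; `analysis/05`) performance rises above
  chance with a growing pair-conditional afferent bias without reaching
  the reliable (≥ 85%) regime — that requires the full-scale horizon
  (400 afferent cells, 800 trials).
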