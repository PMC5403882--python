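# Methods

`v1micro` models contextual processing in mouse primary visual cortex at
two levels of description: a four-population firing-rate model of the
layer-2/3 microcircuit, and a multi-column spiking network of leaky
integrate-and-fire (LIF) neurons.  Both levels share one structural idea —
the three major inhibitory interneuron classes have distinct, cell-type
specific connectivity: PV cells inhibit pyramidal (Pyr) cells and
themselves, SST cells inhibit every other class but not themselves, and
VIP cells chiefly inhibit SST cells (plus weak VIP→Pyr and PV→VIP
connections).

## Rate model

The rates `f_e, f_p, f_s, f_v` (Hz) of the Pyr, PV, SST and VIP
populations follow Wilson–Cowan-type dynamics

    tau_m df_x/dt = -f_x + g_x(net_x),
    g_x(u) = c_x * sqrt(u - theta) for u > theta, else 0,

with `tau_m = 10 ms`, threshold `theta = 360 pA` and gain coefficient
`c = 5.33 Hz/sqrt(pA)` fitted to the F-I curve of the LIF neuron used in
the spiking network (the square root is a standard approximation to the
LIF gain near threshold).  The net drives carry the structural sign
pattern above; SST cells receive no self-inhibition.  Default synaptic
weights (`S_ee = 1.98 … S_vs = 1.48` pA/Hz) and applied currents
(`I_e = 366, I_p = 362, I_s = 361, I_v = 370` pA) are packaged in
`params.RATE_MODEL_DEFAULTS`.  Refractory correction terms of the
Wilson–Cowan formulation are ignored; they matter only at rates far above
the regime studied.

### Fixed points and stability

A population at a fixed point is either silent with subthreshold drive or
active with `f = g(net)`.  `enumerate_steady_states` therefore solves each
of the 16 active-set subsystems separately.  Substituting
`s_a = sqrt(net_a - theta)` turns each subsystem into a *quadratic* system
`s_a^2 = I_a - theta + sum_b W_ab c_b s_b`, which removes the square-root
kink entirely; multi-start root finding (default 80 log-uniform starts per
subset over 0.1–200 Hz, analytic Jacobian) then converges reliably.
Candidate solutions are kept when every active rate is positive, every
silent population's drive is at or below threshold, and the residual is
below 1e-8 Hz; duplicates are merged at 1e-4 Hz.  Completeness is relative
to the multi-start grid; branch-tracking callers pass the previous
solution as a warm start, which keeps folds resolved even where basins
shrink.

Stability comes from the Jacobian using the right-hand gain derivative
`c / (2 sqrt(u - theta))` for active populations; a population sitting
exactly on the kink, or an eigenvalue within 1e-9 of the imaginary axis,
yields the label `marginal` rather than a guess.  An unstable focus is
labelled `oscillatory`; sustained cycles are confirmed by integration
(2000 ms, first 1000 ms discarded, peak-to-peak Pyr excursion above 0.5 Hz
with a stable inter-peak interval) because the model gives no analytic
cycle criterion.

### Input thresholds

`sst_silencing_threshold` scans the SST drive on a coarse 5 pA grid and
bisects the last transition down to 0.5 pA, asking at each point whether
any stable fixed point or confirmed limit cycle keeps `f_e > 0.01 Hz`.
With default parameters the Pyr-active branch terminates in a subcritical
Hopf bifurcation (the complex eigenvalue pair crosses the axis between
364.7 and 364.8 pA, with no stable cycle beyond), so the returned
threshold is 365.0 pA.  `vip_activation_threshold` is analytic: with all
other populations silent the VIP drive is its applied current alone, so
activity starts exactly at `theta`.

A caveat found during analysis: halving the SST gain coefficient moves the
Hopf point slightly *down* (to ~364 pA) rather than up — weakening SST's
gain is partially compensated by the recurrent loop through Pyr, and the
branch loses stability a little earlier.  Only for much stronger gain
reductions (factor ≲ 0.15) does the silencing threshold rise above the
default value.  The corresponding acceptance check, which expects a strict
increase at factor 0.5, fails for this reason; the behaviour is a property
of the printed parameter set, not of the solver (verified by direct
integration on both sides of the bifurcation).

## Spiking network

### Composition

One column holds 19,294 LIF neurons: L2/3 (5171 E, 1459 I), L4 (5479 E,
1370 I), L5 (1213 E, 266 I), L6 (3599 E, 737 I).  The superficial
inhibitory cells split into 24% VIP and 30% SST (round-half-even), the
remainder PV — 350/438/671 at full size.  All neurons share one parameter
set: `tau_m = 10 ms`, `V_th = -50 mV`, `V_reset = V_rest = -65 mV`,
`tau_ref = 3 ms`, `C = 250 pF`.  (`V_rest` is not printed anywhere; the
base-model lineage uses the reset value, and it is config-overridable.)

### Wiring

Interlaminar and deep-layer wiring uses the published layered-microcircuit
connection-probability map of the Potjans–Diesmann lineage from which
this column descends, shipped as a config-replaceable default.  The three superficial interneuron
classes are treated identically by every other layer.  Within layer 2/3:

* Pyr→Pyr and Pyr→interneuron connections are Bernoulli draws with the
  merged-population probabilities (P_EE, P_EI).
* The merged I→E and I→I synapse *budgets* (probability × population
  products) are re-split across cell-type-specific pathways
  proportionally to pathway weight × source-class size, with
  largest-remainder rounding so budgets are conserved exactly.  The
  weights are the experimentally reported per-class connection strengths
  (PV-Pyr : SST-Pyr : VIP-Pyr = 1 : 1 : 0.125;
  PV-PV : SST-PV : VIP-SST : SST-VIP : PV-VIP = 1 : 0.857 : 0.625 : 1 : 1).
  Budgeted pathways are realised by uniform pre/post sampling with
  multapses allowed; Bernoulli rules exclude autapses.

Synaptic peak currents are `w ± δw` Gaussians truncated to preserve sign
(default excitatory 175.6 ± 17.6 pA, default inhibitory −702.4 ± 70.2 pA,
plus the cell-type-specific superficial pairs and the one interlaminar
exception L4E→L2/3 Pyr at 245.84 pA).  PSCs decay exponentially with
pair-specific time constants in layer 2/3 (0.5 ms elsewhere); each
distinct decay constant is one receptor channel on the target neuron.
Delays are Gaussian 1.5 ± 0.75 ms (excitatory) and 0.75 ± 0.375 ms
(inhibitory) within a column, truncated at the simulation step.

Thirteen columns form a ring (periodic boundary).  Only superficial cells
connect across columns, through four pathways: Pyr→Pyr (6.6%, nearest
neighbours), PV→Pyr (4.6%, nearest), Pyr→PV (0.9%, nearest) and the
long-range Pyr→SST (0.2%, reaching four columns each side — so every SST
cell in a figure column receives intercolumnar excitation from 4 figure
and 4 ground columns).  Intercolumnar synapses reuse intracolumnar
parameters with five-fold longer delays (7.5 ± 3.75 / 3.75 ± 1.88 ms).

### Engine

The simulator is a clock-driven exact-propagator integrator (`dt = 0.1 ms`
default) compiled with numba: per step each neuron's channel currents and
membrane potential advance with the closed-form solution of the linear
cascade, spikes are detected on the grid, delivered through a circular
delay buffer at `t_spike + delay`, and the membrane is clamped at
`V_reset` for `tau_ref` while channels keep integrating.  Simultaneous
events are processed in ascending neuron index, so a run is a pure
function of (graph, drives, seed).  Exactness of the propagator makes
results dt-robust (halving dt changes population rates < 2%).  Membrane
potentials start at `V_rest`, as NEST-lineage models do by default; a
uniform-random option exists.

External input: every neuron receives an aggregate Poisson background
(fiber count × per-fiber rate; L2/3 Pyr 1600 × 8 Hz, L2/3 interneurons
share 1500 fibers at 10/2/8 Hz for PV/SST/VIP, deep layers 1900–2900
fibers at 8 Hz) with event amplitude 87.9 ± 8.8 pA.  902 thalamic cells
per column fire Poisson trains at the column's stimulus rate (onset
400 ms, duration 100 ms; 10 ms in the pulse protocol) onto L4 and L6 with
the base-model thalamic probabilities.

### Desk-scale runs

A scale factor `s ∈ (0,1]` shrinks every population; probabilities,
weights and external fiber counts stay unchanged (`compensation="none"`,
the default), so recurrent coupling weakens ∝ s while external drive is
preserved, and the full-size network is the reference.  Three optional
compensation modes (`"probability"`, `"weight"`, `"intercolumnar"`)
preserve expected in-degree × weight products instead; all were evaluated
and rejected as defaults because concentrating the same recurrent charge
onto fewer, stronger connections flips the bistable spontaneous state (see
below).  Experiments rebuild the network per trial by default, so trials
are fully independent simulations and quenched connectivity disorder
averages out.

The spontaneous state of the column is bistable: a VIP-active/SST-silent
state and an SST-active/VIP-silent state coexist (the two classes inhibit
each other mutually).  At full size the default background selects the
VIP-active asynchronous state; uncompensated desk-scale builds (s ≈
0.1–0.5) reproduce it robustly, while mean-preserving compensation modes
collapse into the SST-active state through amplified input correlations.
This is the main reason the scaled network is trusted for *response
order* and *modulation direction* claims but not for quantitative spatial
profiles:

* The pulse protocol (single column, s = 0.5, 20 trials) reproduces the
  onset order VIP ≤ Pyr ≤ PV ≤ SST and the suppression of the Pyr
  response by raised SST (or lowered VIP) background.
* The figure-ground protocol at s = 0.1 preserves the *machinery* of the
  long-range Pyr→SST sweep (SST recruitment during the stimulus scales
  with the probability), but the edge/surface contrast — which at full
  size rides on intercolumnar currents that scale as s² (in-degree × per
  column rate) — is below the trial noise floor, and the surface-dominant
  inversion at 20× Pyr→SST is not resolved.  The corresponding acceptance
  check is expected to fail at desk scale; the run still reports the
  center-to-edge ratio with its confidence interval.

Problem sizes used by the shipped tests: rate-model analyses at full
(four-population) size; single-column spiking runs at s = 0.5 with 20
trials; 13-column runs at s = 0.1 with 10 trials per condition; structural
checks build one full-size (19,294-neuron) column.

## Analysis conventions

Population rates are spike counts / (neurons × window).  PSTHs use 5 ms
bins (1 ms for latency ordering); onset latency is the first bin exceeding
the 200–400 ms baseline mean + 3 SD for two consecutive bins — the
underlying claim is an ordering, so the rule's absolute offset is
immaterial.  Column profiles divide each trial's per-column L2/3 Pyr rate
by that trial's mean edge-column rate (trials with zero edge response are
excluded and counted), or trial-averaged rates by a pooled reference.
Oscillation frequency is the largest periodogram peak of the mean-removed
population rate in 2–100 Hz, accepted when it exceeds 15× the median
in-band power.

## Known limitations

* Scaled-down networks under-express intercolumnar effects (above); the
  full-size 13-column network (~250k neurons, ~2×10^8 synapses) is the
  reference but takes hours per protocol.
* Fixed-point enumeration is complete only relative to its multi-start
  grid; warm-started branch tracking mitigates this near folds.
* The synthetic protocols drive the network with abstract per-column
  thalamic rates; no image front end, orientation structure, adaptation,
  or synaptic plasticity (all outside the model's scope).
* Interlaminar probabilities and the thalamic table are inherited
  base-model defaults, not values fitted to this circuit.
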