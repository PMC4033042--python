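# Methods

## Model overview

`tctsim` simulates a minimal thalamo-cortico-thalamic (TCT) circuit — 1090
Izhikevich point neurons in 16 populations — and analyses its population
mean membrane potentials the way sleep researchers analyse an EEG channel.
Two conditions are first-class: the intact ("baseline") circuit, and a
lesion in which every projection to and from the thalamic reticular
nucleus (TRN) is disabled.  The scientific claim the package operationalizes
is that the intact loop is alpha-dominant (wake-like) while the lesioned
loop slows into theta with a larger relay-cell amplitude (sleep-like).

## Neuron model

The two-variable Izhikevich model with the standard quadratic voltage
equation, recovery variable u, and reset (v ← c, u ← u + d) at a fixed
30 mV cutoff.  Integration is forward Euler with two half-steps of dt/2
for v and one full step for u — the scheme of the model's original
reference code — at dt = 1 ms throughout.

Four packaged parameter rows cover all cell classes:

| mode | a | b | c | d | v₀ | u₀ | τE | τI | I_step | cells |
|---|---|---|---|---|---|---|---|---|---|---|
| RS  | 0.02 | 0.20 | −65 | 6 | −60 | 0 | 5 | 6 | 9  | PY, SS, TCR |
| FS  | 0.10 | 0.20 | −65 | 6 | −70 | 0 | 5 | 6 | 9  | B, IN |
| LTS | 0.01 | 0.20 | −65 | 6 | −70 | 0 | 5 | 6 | 25 | NB |
| TB  | 0.02 | 0.25 | −50 | 2 | −70 | 0 | 5 | 6 | 10 | TRN |

Two reading decisions worth flagging:

* The source table prints the initialization pair under a column header
  ordered "u, v" with values like (−60, 0).  The magnitudes identify the
  first number as a membrane potential; we therefore read v_init = −60/−70
  mV and u_init = 0.  Whether the original runs used u_init = 0 or
  u_init = b·v_init cannot be determined; we use 0 and note that the
  difference washes out within the discarded transient.
* τ columns are read as milliseconds and I as dimensionless model current,
  the conventions of the underlying neuron model.

Synapses are current-based single exponentials with instantaneous rise:
each presynaptic spike adds its weight magnitude to g_E or g_I (by
presynaptic polarity), both drives decay as exp(−dt/τ), and the neuron's
total input current is i_ext + g_E − g_I.  No conductance reversal,
NMDA/GABA_B kinetics, or per-population synaptic diversity — a known
limitation of this model family.

Recorded voltages are clamped at the cutoff on spike samples so population
means are not distorted by numerical overshoot; clamping never feeds back
into the dynamics.

The step-current characterization protocol (drive applied 250–750 ms of a
1000 ms run) plus spike-train metrics (ISI coefficient of variation,
late/early ISI adaptation index, burst grouping with a 10 ms intra-burst
ISI ceiling) verify each mode: RS/FS fire regularly (CV < 0.2 late in the
step), FS outpaces RS at equal drive, LTS adapts (index > 1), TB groups
spikes into ≥ 2 bursts.

## Circuit

Thalamic module: TCR (relay, RS), IN (interneurons, FS), TRN (reticular,
tonic bursting).  Cortical module: layers 2/3 (merged), 4, 5, 6, each with
pyramidal (RS), basket (FS) and non-basket (LTS) populations, plus layer-4
spiny stellates (RS).  Layer 1 is omitted, as is standard for
sparse-neuron layer 1.

**Population sizes are reconstructions.**  The construction rule is known —
cortical proportions from a prior laminar implementation scaled ×10,
thalamic proportions from a prior thalamocortical model scaled ×100, total
1090 — but the literal per-population counts were published in tables that
are not machine-recoverable.  The packaged counts (TCR 100, IN 20, TRN 40;
L2/3 200/30/30, L4 80 PY + 100 SS + 25 B + 25 NB, L5 120/20/20,
L6 240/20/20) honour the rule, an ~80/20 cortical excitation/inhibition
split, and the exact total.

**Wiring.**  Each projection connects every ordered (pre, post) pair
independently with probability P (Bernoulli), excluding self-connections;
at most one contact per pair.  P = 0.25 for all intra-thalamic,
thalamocortical and corticothalamic pathways; intracortical P = 0.1
(reconstructed).  Intra-module delays are fixed at 1 ms; inter-module and
stimulus delays are uniform on [1, 10] ms rounded to integer steps — the
source states a uniform delay but no range, so the range is configurable.

**Weights are reconstructions calibrated as a set.**  Weights C are
"percent of synapses" magnitudes mapped to current units by a single
global `weight_scale`.  The pathway skeleton: stimulus → {TCR, IN};
TCR → {SS4, B4}; SS4 → PY4 and SS4 → PY23; the interlaminar chain
PY23 → PY5 → PY6, closed weakly by PY6 → SS4; corticothalamic feedback
PY6 → {TCR, IN, TRN}; intra-thalamic TCR → TRN, TRN → TCR, IN → TCR;
within-layer PY/B/NB microcircuits.  Corticothalamic feedback is taken
from layer 6 (the deep-layer origin is not recoverable from the source;
L6 is the conventional choice for feedback to first-order thalamus).
Relative magnitudes were tuned, openly, so that the packaged circuit
realizes the target dynamical regime (below); `weight_scale = 0.028` and
stimulus weight 0.4 are the output of the shipped calibration search
(`tctsim.experiments.calibrate_weight_scale`), which picks the smallest
scale that is numerically stable, keeps TCR and PY4 firing between 0.5 and
150 Hz, and yields an alpha-dominant TCR spectrum on at least 2 of 3
calibration seeds.

Two structural choices do real dynamical work and deserve emphasis:
thalamic drive into layer 4 (TCR → SS4 → PY4) is strong while L4
recurrence (PY4 → PY4) and the cortical return onto L4 (PY6 → SS4) are
weak.  This makes layer 4 follow its thalamic driver instead of the
slower intracortical rhythm, which is what lets the baseline PY4 spectrum
sit in alpha alongside TCR.

## Stimulus

Homogeneous Poisson sources at 25 Hz — the resting discharge rate of
retinal ganglion cells — generated by Bernoulli thinning on the 1 ms clock
(per-bin spike probability rate·dt; approximation error ~2.5% at 25 Hz,
immaterial for band analysis).  The number of independent sources is not
recoverable from the source material; the default is one source per target
neuron (120), each wired all-to-all to every TCR and IN cell.  Source and
network weights are the two calibration degrees of freedom.

## Engine

A synchronous clock-driven loop: per step, (1) synaptic drives decay and
matured spikes are injected, (2) all neurons advance one Euler step,
(3) population means of the clamped voltages are recorded, (4) new spikes
enter a circular delay buffer (a spike at step t with delay k affects its
target at step t + k, before that step's update), (5) fired neurons reset.
Delivery and reset order is fixed so that a scalar event-by-event
reference simulation reproduces the vectorized engine bit-for-bit; the
test suite enforces this on single neurons and a hand-wired 3-neuron loop.

Multi-run experiments derive per-run seeds from one master seed via
`numpy` SeedSequence spawning, with separate streams for wiring and
stimulus so that lesioning (which only disables projections) never
perturbs the stimulus realization.  Connectivity is redrawn each run by
default (whether the original three runs re-drew wiring is unstated;
configurable).  Numerical blow-up aborts with the offending population and
step rather than propagating NaNs.

## Spectral chain

Protocol order is fixed: drop a 2 s transient, decimate 1 kHz → 200 Hz by
stride (no anti-alias filter — the source describes the traces as sampled
at 5 ms intervals), apply an order-10 Butterworth band-pass over 1–16 Hz
designed in second-order sections and run forward–backward (zero phase;
"order 10" is the design order, and the bidirectional pass doubles the
effective roll-off), then a Welch periodogram: 100-sample Hamming windows
(half the sampling frequency), 50% overlap, per-segment mean detrending
(the raw traces sit near −60 mV), zero-padded to 800 FFT points → 0.25 Hz
grid.  Band powers integrate the PSD over delta/theta/alpha/sigma; the
dominant frequency is the PSD argmax over 1–16 Hz.  Classification is a
pure function of the dominant band: alpha → wake-like, delta or theta →
sleep-like (theta included because the lesioned circuit peaks there),
otherwise indeterminate.

The three run traces are averaged **before** the PSD (the alternative —
averaging three PSDs — is a documented open reading of the protocol; we
follow the text's "spectra of the averaged mean membrane potential").

Amplitude is summarized as the standard deviation of the unfiltered 200 Hz
trace over the analysis window; "amplitude of oscillation" in the source
is a visual judgement, and the SD is its simplest quantitative proxy.

## What the experiments show

With the packaged calibrated configuration and the full protocol
(3 × 30 s, master seed 0): baseline TCR peaks at 9.75 Hz (alpha band
dominant, wake-like) with SD 6.6 mV; after the TRN lesion the TCR peak
falls to 6.25 Hz (theta, sleep-like) with SD 9.5 mV.  PY4 follows in both
conditions.  The mechanism in this implementation: the TCR–TRN negative
feedback loop paces the relay cells at alpha; removing it both disinhibits
TCR and hands rhythm control to the excitatory corticothalamic loop
(TCR → L4 → L2/3 → L5 → L6 → TCR), whose spike-frequency adaptation sets a
slower relaxation rhythm of larger amplitude.  Consistent with the source
study, the lesioned spectrum slows only into theta, not delta — true
slow-wave dynamics would need burst-mode relay cells and neuromodulatory
state switching, which are out of scope.

## Determinism and seeds

Every stochastic element (wiring, stimulus trains, stimulus delays) is
driven by explicitly derived generator streams; identical (configuration,
master seed) pairs reproduce spike records bit-for-bit.  Reports carry the
configuration digest and seed needed to regenerate them.

## Problem sizes used in the shipped checks

The end-to-end tests and the acceptance script run the full protocol
(1090 neurons, 3 × 30,000 steps per condition, ≈ 30 s of compute per
condition); unit and property tests use seconds-long simulations, small
purpose-built circuits, or closed-form cases.  Calibration uses 10 s
single-run probes per candidate.

## Known limitations

* Band-power dominance of PY4 at baseline sits close to the theta/alpha
  boundary; on a minority of master seeds the PY4 (not TCR) dominant band
  flips to theta even though its spectral peak stays near 9.5 Hz.
* No synaptic plasticity, no conductance synapses, no burst-mode relay
  dynamics, no dendro-dendritic interneuron coupling, single shared
  synaptic kinetics for all excitatory and all inhibitory projections.
* The stimulus is stationary; rate-modulated input (e.g. the 11–20 Hz
  awake-state retinal estimates) is available as configuration only.
* Population counts and weights are documented reconstructions, not
  recovered values; conclusions should be read as properties of this
  calibrated realization of the architecture, not of the original
  parameterization.
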