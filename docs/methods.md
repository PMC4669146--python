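# Methods

## Network model

The network has four populations: N_vis visible excitatory neurons,
N_hid hidden excitatory neurons, and one pool of N_inh inhibitory
neurons per layer.  Visible and hidden neurons are connected
reciprocally all-to-all (feedforward matrix **W**, feedback matrix
**Q**); each inhibitory pool is connected reciprocally with every
excitatory neuron of its layer with fixed, uniform weights.  There are
no lateral connections between excitatory neurons and no plasticity at
inhibitory synapses.

Neurons are conductance-based leaky integrate-and-fire units.  Membrane
potential obeys

    τ_m dV/dt = (V_rest − V) + g_e (E_e − V) + g_i (E_i − V) + g_a (E_i − V)

with conductances in units of the leak conductance.  Each synaptic event
increments g_e or g_i, which decay with τ_e and τ_i; crossing threshold
emits a spike, resets V, and starts an absolute refractory period.
Excitatory neurons additionally carry a spike-frequency adaptation
conductance g_a (incremented at each spike, decaying with τ_a, reversal
at E_i); inhibitory neurons do not adapt.  Integration is
exponential-Euler at dt = 0.1 ms; every delivered spike arrives one
synaptic transmission delay (2 ms) after emission, implemented with a
ring buffer.  A one-neuron version of the same integrator
(`simulate_constant_drive`) is checked against the closed-form LIF f-I
curve to within 2%.

Default neuron parameters (τ_m = 20 ms, V_rest = −70 mV, V_thresh =
−54 mV, V_reset = −60 mV, refractory 2 ms, τ_e/τ_i = 5/10 ms, reversals
0/−80 mV, τ_a = 100 ms) follow the standard conductance-LIF family used
in cortical network modelling.  They are reconstructions — reasonable
values of the family, not published ones — and every value is a config
field.

External input is delivered as excitatory conductance events (weight
`w_ext` per input spike) to visible neurons only, during a stimulation
window at the start of each trial; a current-like mode (fixed driving
force, no shunting) is available via `input_as_current`.  The trial
itself runs 65 ms so that the feedforward and feedback bouts can play
out after the input ends.

## Stimulus pipeline

Images are mean-subtracted against a dataset mean and split into ON/OFF
channels: ν_ON = max(0, ν), ν_OFF = max(0, −ν).  The split is lossless
(ON − OFF recovers the signed vector) and all rates are non-negative.
Rates are encoded as homogeneous Poisson trains at `rate_scale`
(spikes/s per unit pixel value) over the `stimulus_duration` window.
Defaults (800 s⁻¹, 10 ms) give a unit-intensity pixel 5–10 input spikes
per window, producing an initial visible bout of a few spikes per driven
neuron.  The stimulation window and trial length imply the three-bout
timing: visible activity 0–15 ms, hidden 5–20 ms, feedback-driven late
visible spikes behind that.

A contrast filter for natural-image patches accepts a patch when the
mean of its ON/OFF rate vector (equivalently the mean absolute signed
value) is at least 0.06.  The signed values are approximately zero-mean
after preprocessing, so any reading of "average value" other than the
absolute one would make the threshold vacuous; "at least" means the
boundary value passes.

## Plasticity

Feedforward synapses follow additive all-pairs STDP; feedback synapses
follow the temporally reversed rule (aSTDP).  Because the pre/post roles
of a visible–hidden pair swap between the two connection directions,
both rules reduce to one kernel in visible/hidden spike times —
potentiation +e^(−Δt/τ+) when the hidden spike is later, depression
−e^(−|Δt|/τ−) otherwise — so Δw_ij/η = Δq_ji/ζ holds exactly, per pair
and per trial.  Updates are accumulated over a trial and applied once at
trial end (the derivation treats the trial as a unit, and this removes
within-trial order dependence), then clipped: signed mode to
[−w_max, w_max], non-negative mode to [0, w_max].  Plasticity operates
on raw weights; homeostatic offsets/factors modify only the effective
weights used in simulation.

Tie-breaking: simultaneous visible/hidden spikes count as depression in
the mirrored kernel for *both* directions.  The printed aSTDP pair rule
assigns ties to potentiation; the two conventions differ only on the
measure-zero simultaneous case, and `astdp_pair_sum` implements the
aSTDP rule as printed while the trial update follows the mirrored
kernel.  τ+ pairs with the potentiation branch in both rules, matching
the mirrored kernel profiles.

Two analytic limits are implemented as oracles (never used in
training): the bout-limit prediction ΔW = η(βx − γx̂)y⊺ with
β = e^(−Δt1/τ+), γ = e^(−Δt2/τ−), which the spiking update matches to
machine precision when all spikes sit exactly at three instants; and the
scaled autoencoder rule ΔW = (x − x̂/α)y⊺, to which the bout rule is
exactly proportional when γ/β = 1/α.  The tied-weight scale is
identified as α ≈ ζ/η, with symmetric initialization Q = (ζ/η)W⊺.

## Homeostasis

Each hidden unit keeps a running average A_j of whether it fired at
least once per trial, A_j ← (1−d)A_j + d·fired, and after every trial
moves its synaptic offset φ_j (additive mode, signed weights) or scaling
factor Φ_j (multiplicative mode, non-negative weights, floored at 0) by
κ(ρ − A_j).  Scaling acts only on feedforward excitation of hidden
units; visible responses to external input and to feedback are never
scaled.  The homeostatic update runs after the plasticity update each
trial (the order is a design choice; at these rates the two barely
interact within a trial).

Defaults: d = 0.005 (an effective window of ~200 trials).  The
equilibrium jitter of A_j under Bernoulli firing is σ ≈ √(ρ d/2), which
at d = 0.005 stays near 0.35ρ even for ρ = 0.02 — comfortably inside
the ±0.5ρ band the convergence tests require.  The bars experiment
overrides d to 0.01 and κ to 0.1: with only 16 stimuli, units knocked
below threshold by depression must re-find their operating point within
a few hundred trials, and the faster integral loop shortens those silent
phases.  Whether reconstruction-phase visible activity should also be
scaled is left open by the model description; here only visible→hidden
efficacy is scaled.

## Trainer

Per presentation: Poisson-encode the stimulus → simulate one trial with
effective weights → apply the mirrored-STDP update (clipped) → update
homeostasis from hidden firing.  Two modes pair the weight constraint
with the homeostasis variant: `signed_additive` (bias-like offsets,
weights of either sign) and `nonneg_multiplicative` (Dale-compliant
non-negative weights, multiplicative factors).  Every `eval_every`
presentations the test set is presented with plasticity *and*
homeostasis frozen (freezing both is a design choice; the model
description only freezes plasticity) and metrics are recorded;
checkpoints go to HDF5.

Randomness: one master seed is split via `SeedSequence` into independent
streams for weight initialization, presentation order, per-trial
encoding (keyed by presentation index), and per-test-image encoding
(keyed by image index).  Test inputs are therefore frozen across
evaluations, and a run resumed from a checkpoint is bit-identical to an
uninterrupted one.  Initial weights are uniform on a small interval
(truncated at 0 in non-negative mode); symmetric initialization sets
Q = (ζ/η)W⊺ exactly.

A runaway-excitation guard aborts training when a trial's total spike
count exceeds `runaway_factor` (default 20) times the median of the
first 100 trials — strong positive feedback through **Q** is the
model's known failure mode.  In small refractory-capped networks the
saturation ceiling may sit below 20× baseline, in which case a tighter
configured factor is needed for the guard to be meaningful.

## The bars experiment

The reference desk-scale run (`bars_train_config`): 16 single-bar
stimuli on an 8×8 grid (each bar unit intensity, mean-subtracted against
the single-bar mean, ON/OFF split to 128 visible neurons), 16 hidden
units, 8 inhibitory neurons per pool, non-negative/multiplicative mode,
independent initialization, 5,000 presentations, ρ = 1/16 (one bar per
unit), η = ζ = 10⁻³, τ+ = 20 ms, τ− = 30 ms, w_max = 0.4.

Parameter reasoning: `w_ext` = 1.0 makes a bar pixel's ~7 input spikes
drive its visible neuron to 3–5 spikes; hidden competition
(E→I 0.5, I→E 0.8 in the hidden layer) discourages duplicate bar
assignments; visible-layer inhibition (0.15/0.3) and a weak adaptation
increment (0.05) terminate the initial bout without silencing the
feedback echo.  `feedback_gain` = 8 scales feedback efficacy during
simulation only: with at most one or two active hidden units per
stimulus (versus hundreds in a full-scale network), unscaled feedback
could never bring any visible neuron back to threshold, and without a
late bout the depression term of the learning rule is inoperative.  The
learned **Q** itself — and every metric computed from it — is
untouched by the gain.  τ− > τ+ weights depression from the late bout
(which sits further from the hidden spikes in time) more heavily,
sharpening the pruning of weakly correlated inputs.

Measured at these conditions (master seed 1): mean corr(ν, Q⊺z) ≈ 0.61
over six frozen Poisson draws of each bar, 12 of 16 bars recovered as
the dominant receptive-field structure of some hidden unit, and weight
symmetry rising from |corr| ≈ 0.01 to ≈ 0.93.  Outcomes vary noticeably
with the master seed (other seeds give correlations of roughly
0.35–0.6): with 16 units for 16 bars, duplicate assignments are
quasi-stable under rate homeostasis and only the reconstruction-driven
depression breaks them, slowly.  This smallness artifact — not present
at full scale, where thousands of units cover the feature space many
times over — is the main caveat when extrapolating from the bars run.

## What the synthetic generator does and does not emulate

Bars/blobs/strokes stimuli have known sparse latent structure, exercise
the ON/OFF pipeline, Poisson encoding, three-bout dynamics, mSTDP and
homeostasis end to end, and make receptive-field recovery checkable by
template correlation.  They do not reproduce the statistics of natural
images (1/f spectra, whitening, contrast distribution) or of MNIST
(correlated strokes, class structure), so passing the bars run shows the
learning machinery works, not that full-scale receptive fields
(Gabor-like filters, digit strokes) will match published figures.  The
full-scale pipelines (IDX reader + 14×14 down-sampling; patch extraction
+ 0.06 contrast filter) are implemented and the trainer supports the
corresponding sizes, but runs at those scales are out of desk scope.

## Numerical choices and degenerate cases

- Exponential-Euler at dt = 0.1 ms; refractory enforced in integer
  steps, so the minimum interspike interval is t_ref + dt.  Halving dt
  shifts ensemble spike counts of the excitatory populations by under
  5%; the small inhibitory pools fire in synchronized waves, so their
  counts are quantized in steps of N_inh and converge more coarsely.
- Pearson correlation with a constant vector (e.g. a stimulus that
  evoked no hidden spikes) is undefined; such pairs contribute 0 to the
  reconstruction average (worst-case-neutral) and are counted in a
  diagnostic.  Constant pairs in hidden-unit correlation histograms are
  skipped, with the skip count reported.
- Bout boundaries (for diagnostics only — plasticity is all-pairs and
  never uses them) default to the end of the stimulation window; empty
  bouts yield NaN separations, and the bout-rule oracle refuses NaN
  separations only when the corresponding count products are nonzero.
- Receptive-field rendering normalizes per unit by the largest absolute
  value, leaving all-zero units at zero rather than dividing by zero.
- Weight clipping bounds are enforced after each trial update; the
  mirror-symmetry identity Q = (ζ/η)W⊺ is exact only while no entry is
  clipped.

## Known limitations

- No dendritic compartments: the distal/proximal distinction that
  motivates the different feedback plasticity is not simulated, only its
  consequence (the aSTDP rule).
- Lifetime sparsity only: synaptic scaling controls how often each unit
  fires, not how many units fire per stimulus; population sparsity would
  need learned lateral interactions.
- Uniform fixed inhibition; no short-term dynamics, conduction-delay
  heterogeneity, or triplet/voltage/multiplicative STDP variants.
- The two full-scale experiments (5,000 hidden units × 100,000 MNIST
  presentations; 500 × 300,000 whitened patches) are supported by the
  code paths but not validated here; published headline numbers for
  those runs are not desk-reproducible.
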