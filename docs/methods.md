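# Methods

`spikegaze` classifies near-eye event-camera streams into saccades and
fixations with a convolutional spiking neural network (SNN), and
accounts for the computational cost of that network against an
equivalent dense artificial network.  This note records the models, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## Event model and simulator

An event camera pixel emits an event when its log intensity moves a
full contrast threshold θ away from a per-pixel reference level:

    L(x, y, t) − L_ref(x, y) ≥ θ   →  event (+1),  L_ref += θ
    L(x, y, t) − L_ref(x, y) ≤ −θ  →  event (−1),  L_ref −= θ

The emulator applies this rule to a rendered frame sequence.  When one
frame step crosses k thresholds, k events are emitted with timestamps
linearly interpolated inside the frame interval, and the reference
advances by exactly kθ rather than resetting to the current value; this
keeps the threshold rule exact across multiple crossings (the standard
DVS-emulation convention) and makes event counts conserve total
reference advancement exactly.  Spurious background activity is modelled
as a homogeneous Poisson process per pixel (default 0.1 Hz/px, within
the 0.01–1 Hz/px range typical of real sensors) with equiprobable
polarity.  There is no per-pixel refractory period.

The scene is a dark pupil disc inside an iris disc on a bright sclera,
rendered with 1-px anti-aliased edges (intensities 0.08 / 0.35 / 0.90,
all strictly positive so the log exists).  Gaze kinematics alternate:

* **fixations** — 50–600 ms, held position plus a Gaussian drift random
  walk.  The default drift step (2×10⁻⁴ of the sensor short side per
  1 kHz sample) makes the pupil wander a fraction of a pixel over a
  typical fixation, consistent with ocular drift being orders of
  magnitude slower than saccades.
* **saccades** — 20–200 ms, straight-line displacement with a
  raised-cosine velocity profile v(τ) ∝ sin²(πτ/d), which is smooth,
  symmetric, and integrates in closed form to the commanded amplitude.
  Amplitudes default to 15–45 % of the sensor short side.  A
  configurable peak-velocity cap (default 40 short-sides/s) is the
  pixel-space analog of the ~700°/s physiological ceiling; the sensor's
  deg/px scale is not specified anywhere, so this is an explicit
  configuration value, and saccades whose raised-cosine peak 2A/d would
  exceed it have their amplitude clamped with a warning.

These choices produce the physical signature the classifier exploits:
saccade windows are dense event bursts along the moving disc boundary,
fixation windows are sparse drift/noise events.  The generator tags
segments with synthetic user ids round-robin so the user-wise train/test
split is meaningful.

**What a green synthetic benchmark establishes.** That the full chain —
encoding, spiking dynamics, surrogate-gradient training, rate decoding —
learns a strongly density-separable two-class problem at a reduced
geometry.  It does not establish performance on real recordings:
the synthetic scene has no eyelids, eyelashes, blinks, specular
reflections, smooth pursuit, or inter-subject appearance variation, and
its class separation is cleaner than manually annotated data.

## Spike-tensor encoding

A stream segment becomes a binary tensor S ∈ {0,1}^(2×H×W×T) with 1 ms
bins by default: an event at relative time t′ sets cell
(channel(p), y, x, ⌊t′/Δt⌋) to 1.  Cells saturate (assignment, not
count); polarity −1 maps to channel 0 (OFF) and +1 to channel 1 (ON);
bin windows are half-open, so an event exactly at T·Δt is dropped (and
tallied).  T = ⌈window·1000/Δt⌉, so an N-ms window at the default bin
width gives T = N steps and an effective frame rate of 1000/N.

## Neuron model

All weighted stages use current-based leaky integrate-and-fire
(CUBA-LIF) dynamics, per step:

    u[t] = (1 − α_u)·u[t−1] + x[t]
    v[t] = (1 − α_v)·v[t−1] + u[t] + b
    s[t] = Θ(v[t] − ϑ)
    v[t] ← v[t]·(1 − s[t])

with per-layer shared parameters.  Defaults: α_u = 0.25, α_v = 0.03,
ϑ = 1.25, b = 0 — chosen as reasonable package defaults (the source
material gives none) and exposed in configuration.  Decays convert to
time constants by α = 1 − exp(−Δt/τ).  State is zeroed between samples.
α_u, α_v and ϑ are learnable per layer; the bias is not learnable by
default — when it is, training can satisfy the rate targets through the
output bias alone with dead hidden layers, a degenerate optimum we
observed directly.

A plain LIF cell with optional recurrence and a proportional
−R·U reset term is included as a reference model only; the −R·U term's
normalization is a modelling convention, applied here to the
previous-step membrane.

## Training

The forward pass always uses the exact Heaviside spike.  The backward
pass substitutes a surrogate kernel for its derivative,
exp(−|v−ϑ|/σ)/(2σ) by default, with a fast-sigmoid alternative.  The
kernel width defaults to σ = ϑ: with the narrower σ = ϑ/2 sometimes
used elsewhere, runs on some seeds stall at the loss floor of a fully
silent output (the gradient reaching quiet deep layers decays like
exp(−|v−ϑ|/σ) per stage); the wider kernel keeps enough gradient
flowing to recover from silence, at the cost of a blurrier credit
assignment near the threshold.  The reset multiplication is detached in the backward pass
(the standard surrogate-gradient convention).  For verification, a
"soft" mode replaces the spike by the kernel's antiderivative and keeps
every term differentiable; on that relaxation, backprop-through-time
agrees with central finite differences to 10⁻³ relative, which is the
package's evidence that the hard-mode gradients are implemented as
specified.

The spike-rate loss drives the mean output rates toward r_true = 0.2
(correct class) and r_false = 0.03 (other class); both are
configurable and recorded in every run manifest.  Optimization is Adam
(lr 0.01, batch 8), 100 epochs by default (20 in the scaled benchmark).
A seeded 10 % validation split is held out of the training segments,
and the weights of the epoch with the highest validation accuracy are
kept (ties resolve to the later epoch).  Spiking training trajectories
oscillate — the shared per-layer thresholds and decays adapt quickly
and keep shifting every layer's operating point — so selecting by
validation accuracy is substantially more stable than keeping the last
epoch; both the split and selection are seeded and can be disabled.
Prediction is the output neuron with the larger mean rate; exact ties
resolve to class 0 (fixation), so a fully silent output predicts the
sparse class.

Dense layers carry unit dropout (p = 0.05; a sampled unit's whole spike
train is zeroed within a sample, inverted scaling), per-output-unit
weight normalization w = g·v/‖v‖, and per-input integer synaptic delays
clipped to [0, min(T−1, 62)].  Delays are applied in the forward pass
as bin shifts; delay *learning* is not implemented — delays default to
zero and can be set explicitly.  Weights are initialized zero-mean
Gaussian at scale gain/√fan_in (gain 2.5 by default, fixed together
with the surrogate width by a small grid over independently generated
synthetic worlds): small enough that the output does not saturate at
initialization, large enough that every layer is active and reachable
by gradient.

## Complexity accounting

Accounting runs over the outputs of the seven computational stages
(conv1, pool1, conv2, pool2, dense1, dense2, readout) under a uniform
fan-out convention that ignores border effects — the only convention
consistent with the reference table's exact products:

    fan_out(conv) = k_x·k_y·c_out/(s_x·s_y);  pool = 1;  dense = width
    MACs(node k) = units(node k−1) × fan_out(stage k),  k ≥ 1
    synops(node k) = mean events(node k−1) × fan_out(stage k)

The first conv node has no upstream accounting node; its MAC cell
mirrors its own unit count and is excluded from the MAC total, while
the activation total includes all seven nodes.  Event sparsity is
total activations / total events; synapse sparsity is total MACs /
total synops; both are reported rounded to 2 decimals.  The energy
model is E(F) = T·(f_r·E_AC·O_AC + E_MAC·O_MAC), with default energies
0.9 pJ (AC) and 4.6 pJ (MAC), the common 45 nm figures — configuration
values, not measurements.

## Numerical choices

* Timestamps are integer microseconds; window/bin parameters are
  milliseconds at the API surface, converted exactly.
* All intervals are half-open [t0, t1); adjacent windows never share an
  event.
* Shapes propagate as out = ⌊(in − k)/s⌋ + 1 for unpadded convolutions
  and out = ⌈in/2⌉ for 2×2 stride-2 pooling (ceil mode); both are
  forced by the reference shape table.  No layer has a bias term
  (forced by the parameter counts).
* Spiking max-pool is a logical OR per bin (max ≡ OR on binary spikes);
  its backward pass routes gradient to the window argmax.
* Training runs in float32 for speed; gradient checks run the float64
  soft mode.  Every random draw descends from one seed via
  `numpy.random.SeedSequence`.

## Training variance

Desk-scale surrogate-gradient training of this architecture has
appreciable run-to-run variance: across independent generator/training
seed pairs at the benchmark scale (64×64, 150 segments per class,
20 epochs) held-out accuracy typically lands between ~0.85 and ~0.95,
even though a single-feature density classifier separates the same
windows at ~0.97–1.00.  The residual errors are almost entirely
low-event saccade windows (a 33 ms window at the start of a long
saccade catches only the slow onset of its raised-cosine velocity
profile).  Validation-based epoch selection removes the worst of the
final-epoch lottery; the remaining spread is a property of the method
at this scale and is reported rather than hidden.

## Known limitations

* The SNN engine is NumPy BPTT, adequate for desk-scale geometries;
  full-geometry (360×260) training is out of its intended range, though
  all full-geometry *arithmetic* (shapes, parameters, MACs) is exact.
* Delay learning and recurrent topologies are not implemented.
* The synthetic benchmark's accuracy ceiling reflects its clean class
  structure; it stands in for, and does not estimate, real-data
  accuracy.
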