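# Methods

This note documents the models implemented in `ctmonitor`, the choices
made where the design was open, what the synthetic generators do and do
not emulate, and the numerical conventions the tests rely on.

## Scope and computational backend

The toolkit covers two complementary approaches to CT monitoring:

1. **Next-frame prediction** with a convolutional LSTM, used for anomaly
   detection through reconstruction error: a model trained only on
   normal image sequences reconstructs them well, while unusual events —
   an appearing structure, sudden growth — produce elevated errors.
2. **Binary classification** of CT volumes (3D CNN) and slices (2D CNN),
   with the Hounsfield-unit preprocessing chain standard in lung CT.

All networks run on a small NumPy engine (`ctmonitor.nn`) written for
this package: stride-1 "same" convolutions in any spatial rank
(evaluated as one BLAS contraction per kernel offset), a ConvLSTM layer
with full backpropagation through time, non-overlapping max pooling,
global average pooling, batch normalization, dense/dropout layers, and
an Adam optimizer.  Every layer's backward pass is verified against
central finite differences in the test suite, and the convolution and
ConvLSTM forward passes are cross-checked against independent
scipy-based references.  The engine is deliberately small: it supports
exactly what the three architectures need, trades peak speed for
auditability, and keeps the entire computation deterministic under a
single seed (initialization, shuffling, dropout masks).

## Convolutional LSTM cell

The cell follows the standard LSTM gating discipline with convolutional
gates over the concatenation `[h_{t-1}, x_t]` (hidden state first):

    f_t = sigmoid(w_f * [h_{t-1}, x_t] + b_f)
    i_t = sigmoid(w_i * [h_{t-1}, x_t] + b_i)
    o_t = sigmoid(w_o * [h_{t-1}, x_t] + b_o)
    g_t = tanh   (w_c * [h_{t-1}, x_t] + b_c)
    c_t = f_t . c_{t-1} + i_t . g_t
    h_t = o_t . act(c_t)

Conventions chosen where the formulation is open:

- **No peephole connections** — the gates contain no cell-state term.
- **Candidate activation tanh** — the classical form; selectable.
- **Output activation `act` defaults to ReLU**, matching the activation
  assigned to the recurrent blocks of the frame predictor; the classical
  tanh is selectable.  Only the cell output is affected, not the
  candidate.
- **"Same" padding, stride 1**, so hidden maps keep the frame size —
  required for a model that must emit full-resolution frames.
- Initialization: Glorot-uniform kernels, zero biases except the forget
  gate bias at 1.0 (the usual carry-friendly start).

`ctmonitor.convlstm_core` is the purely functional single-sample
reference (per-gate kernels, explicit `cell_step`); the trainable
`nn.ConvLSTM2D` layer stores the four gates fused for speed and must
agree with the core exactly, which the tests assert.

## Frame predictor

Three ConvLSTM blocks (kernels 5x5, 3x3, 1x1; all returning full
sequences), batch normalization after the first two, and a final 3-D
convolution (3x3x3, one filter, sigmoid) over the (time, height, width)
stack.  Output therefore has the input's shape with intensities in
[0, 1].  At full scale each recurrent block uses 64 filters; the first
block then holds 4*(5*5*(1+64)*64 + 64) = 416,256 parameters.

- **Training is teacher-forced** on shifted pairs: input frames
  0..T-2, target frames 1..T-1 (a 20-frame sequence gives 19 steps).
  Multi-frame prediction at inference is autoregressive: each predicted
  frame is appended to the context before predicting the next.
- **Loss**: pixel-wise binary cross-entropy on [0, 1] intensities
  (mean squared error selectable).  The accompanying "accuracy" metric
  is pixel-wise agreement after binarizing prediction and target at 0.5.
- **Optimizer**: Adam, default step size 1e-3.  The desk-scale training
  profile used throughout the tests raises the step size to 3e-3 — the
  narrow networks tolerate the larger step, and the profile's 30-epoch
  budgets are best spent with it.
- **Anomaly scoring**: per-frame mean squared one-step reconstruction
  error; the aggregate score is the mean over frames.  A sequence is
  flagged when its aggregate exceeds mean + k*sd (default k = 3) of the
  aggregate scores on a clean calibration set.

## Volume and slice classifiers

The 3D classifier stacks four Conv3D blocks (3x3x3 kernels, ReLU;
filters 64, 64, 128, 256 at full scale), each followed by 2x2x2 max
pooling (window chosen as the minimal non-trivial size consistent with
four pooling stages on small volumes) and batch normalization (placed
after pooling), then global average pooling, a 512-unit ReLU dense
layer, dropout (default fraction 0.3), and a single sigmoid unit.  The
decision threshold is 0.5.  The model boundary uses the
(samples, width, height, depth, 1) convention; volumes stored
depth-first are adapted by an explicit axis transpose.

Training runs up to 100 epochs with per-epoch shuffling and early
stopping (validation loss, patience 15, best weights restored).  With a
constant monitored metric the policy stops after exactly patience+1
epochs.

The 2D classifier uses two Conv2D blocks (128 then 64 filters at full
scale, 3x3 kernels — the smallest standard choice, unspecified in the
source architecture), each with 2x2 max pooling, then flatten and a
2-unit softmax head with no hidden dense layer in between.  Slice input
size is 64x64 after resizing.

## Preprocessing chain

- **HU windowing**: clip to [hu_min, hu_max], then map affinely to
  [0, 1].  Default window [-1000, 400] HU (air to soft tissue), the
  standard lung window.  Monotone by construction.
- **Orientation**: one 90-degree counter-clockwise in-plane rotation of
  every axial slice (an exact permutation of voxels).  In-plane rotation
  was chosen over a volume axis transpose; the convention is fixed here.
- **Resizing**: trilinear interpolation (order-1 spline via
  scikit-image).  Linear interpolation is convex, so resized values
  cannot leave the input's range; higher orders would.  Default target
  64x128x128 (depth, height, width); the desk-scale profile uses 32^3.
- **Augmentation**: one in-plane rotation per volume with the angle
  drawn uniformly from {-20, -10, -5, 5, 10, 20} degrees, bilinear
  interpolation, zero fill.

## Synthetic data

**Moving glyphs** emulate the classic bouncing-digit video benchmark:
1-3 procedurally drawn sprites (disc, ring, cross, bar, hollow square;
binary intensity) translate with constant velocity — speed drawn from
[1, 3] px/frame, direction uniform — and reflect elastically at the
borders (`p' = 2b - p`, velocity negated).  Defaults: 20 frames of
64x64 pixels, two glyphs.  An adapter accepts external sprite sets
(e.g. 28x28 digit images) so no download is required.  Injected
anomalies: `appear-blob` overlays a bright soft-edged blob (radius
size/6, intensity 0.9) from an onset frame onward; `sudden-growth`
progressively dilates the frame content.  Frames before the onset are
bit-identical to the input.

**Lung phantoms** are HU-valued volumes: air background (-1000 HU), a
soft-tissue body ellipsoid (+40 HU), two lung ellipsoids (-800 HU,
additive Gaussian noise with sd 20 HU), and optionally a noise-free
spherical nodule (+50 HU) strictly inside a lung.  The values are
physically plausible for lung CT and, deliberately, linearly separable
after windowing, so classifier tests measure learning machinery rather
than borderline contrast.  The noise field is drawn before the nodule
is stamped; under a fixed seed the with/without-nodule pair differs
exactly on the nodule sphere.  Labeled sets place round(n*rate)
nodules (round-half-even, for reproducible counts) with jittered
centers and radii, shrinking both deterministically when a draw would
poke out of the lung.

What the generators do **not** emulate: scanner noise spectra and
artifacts, respiratory/cardiac motion, anatomical variability, partial
volume effects, real nodule morphology, or digit-like sprite
appearance.  Passing tests therefore demonstrate that the
architectures, preprocessing and training loops work end to end and can
separate well-posed classes — not that the models reach clinical
performance on real CT data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run a desk-scale profile
chosen so the full pipeline trains in minutes on one CPU: 32x32 frames
with 8-filter recurrent blocks for the predictor; 32^3 phantoms with
8/8/16/32-filter blocks and a 32-unit dense layer for the volume
classifier; 16/8-filter blocks for the slice classifier.  Architecture
contracts (shapes, parameter counts) are always checked on the
full-scale specifications.

- Anomaly experiment: 50 clean training sequences, 30 epochs, scored on
  20 clean + 20 injected held-out sequences.
- Volume experiment: 40 training + 20 validation phantoms, up to 30
  epochs.  Slice experiment: ~500 slices from 63 phantoms, 10 epochs.
- Gate values are mathematically in (0, 1) but saturate to exactly 0 or
  1 in float64 beyond |z| of roughly 37; openness is asserted at
  moderate magnitudes.
- Non-overlapping pooling resolves ties by first occurrence in the
  flattened window; gradient checks use continuous random inputs where
  ties have measure zero.
- BCE probabilities are clipped to [1e-7, 1 - 1e-7]; batch norm uses
  eps 1e-3 and running-stat momentum 0.9.
- All computation is float64; the ConvLSTM layer/core agreement is
  asserted at 1e-6 and the scalar cell oracle at 1e-12.

## Known limitations

- The NumPy engine is single-threaded apart from BLAS; full-scale
  (64-filter, 64x64) training is impractical with it — the full-scale
  specs are exercised forward-only.  Experiment presets therefore
  default to the desk profile, with the full-scale architecture
  selectable.
- Early stopping compares the monitored metric with strict improvement
  (min_delta 0); plateaus count as no improvement.
- The NIfTI reader assumes the on-disk axes are (x, y, z) and reorders
  to (depth, height, width) without general orientation handling
  (no sform/qform reinterpretation).
- `run_experiment` presets reproduce example/epoch counts of the study
  designs they are named after, but always on synthetic data; two of
  the source tables are garbled, and the adopted readings (353
  examples / 100 epochs; 3532 examples with 10 and 20 epochs) are
  marked in the preset docstrings.
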