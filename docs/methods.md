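# Methods

## The explanation problem

Given a trained differentiable model — a classifier producing per-class
scores, or a segmentation network producing a voxel-wise per-class map — and
one input image or volume `x`, the package produces attribution maps: arrays
scoring how much each input element contributed to one scalar summary of the
model's output.  All seven methods are *post hoc*: they require no retraining
and no architecture modification, only forward evaluation and gradients.

### The scalar target

Attribution explains a scalar, never a vector.  For classification the
scalar is the selected class's score.  Two modes exist:

* **logit** (default): the raw pre-softmax score.  Softmax probabilities
  saturate for confident predictions, driving gradients toward zero; the
  logit avoids this.
* **probability**: the softmax of the scores, for users who want the map of
  the calibrated output.

For segmentation the voxel map is reduced by **global average pooling** of
one class channel — the mean over all voxels, or over an optional region
mask.  This converts segmentation into a multi-label classification problem
and lets every classification-era method run unchanged.  By default the
pooling acts on the pre-activation class map (the same saturation argument
as for logits); probability pooling (voxel-wise softmax first) is available.
The reduction is linear, so the target's gradient at the output is simply a
uniform weight `1/N` on the chosen channel (restricted to the mask when
given).

## The seven methods

Notation: `F` is the target scalar as a function of the input, `x_B` the
baseline (all-zero "black" image unless overridden), `A^l` the activation of
layer `l`.

* **Vanilla gradient** — `∂F/∂x`, one backward pass.  Signed, per-channel,
  input resolution.
* **Guided backpropagation** — the same backward pass with the guided-ReLU
  rule: at each ReLU the signal is zeroed where the forward activation is
  ≤ 0 (the ordinary ReLU gradient) *or* where the incoming backward signal
  is ≤ 0 (the guidance).  Applied to every ReLU; other nonlinearities pass
  gradients through unmodified (logged once).  On a ReLU-free model GBP
  equals VG bit-for-bit — a test invariant.
* **Integrated gradients** — `(x−x_B) ⊙ (1/m) Σ_j ∂F(γ(α_j))/∂x` over an
  α-grid of `m` points on the straight line `γ(α) = x_B + α(x−x_B)`.
  Defaults: `m = 64`, midpoint rule, black baseline; left and trapezoid
  rules are exposed.  Completeness `Σ IG = F(x) − F(x_B)` holds up to
  quadrature error.
* **Guided integrated gradients** — an adaptive path from `x_B` to `x`.
  Each step computes per-feature importance `|∂F/∂x_i|` at the current path
  point (∞ for features already equal to the input), then moves the
  least-important frontier features toward their input values until the
  step's L1 quota is covered, accumulating (moved delta × local gradient).
  The quota is `step_fraction` of the **initial** L1 gap — a linear schedule
  that finishes the walk exactly at the step budget, with the quota-boundary
  feature moved partially.  (Covering a fraction of the *remaining* gap
  instead would leave `(1−1/m)^m ≈ 37%` of the path to a single terminal
  extrapolation and was measured to break completeness at the ~19% level;
  the linear schedule keeps it at the few-percent level.)  Defaults:
  `step_fraction = 1/steps`, `steps = 64`, convergence tolerance `1e-9`.
  If the budget is exhausted before the path reaches `x`, the walk snaps to
  `x`, accumulates the final deltas, and records a warning in the map
  metadata — never silently.
* **SmoothGrad** — mean of any base method over `n` samples
  `x + N(0, σ²)`, with `σ = noise_fraction × (max x − min x)`.  Defaults
  `n = 25`, `noise_fraction = 0.1` (conventional values; the method's
  literature offers no canonical setting).  Seeded and bit-reproducible;
  `σ = 0, n = 1` reproduces the base method bit-exactly.
* **Grad-CAM** — at a chosen layer, channel weights
  `α_k = (1/N) Σ_spatial ∂F/∂A_k`, map `ReLU(Σ_k α_k A_k)` at the layer's
  native resolution, nonnegative by construction.  The sum runs over the
  feature channels of the chosen layer (one `α` per channel); the default
  layer is the deepest one with spatial extent.  Dense layers are rejected.
* **Guided Grad-CAM** — the Grad-CAM map is linearly interpolated
  (bilinear/trilinear) to the input grid and multiplies every channel of
  the GBP map.  Tests pin this to the manual composition bit-for-bit.

Multi-channel inputs (the four MRI modalities) keep per-channel
attributions throughout; channel reduction (max of absolute values) happens
only at rendering.

## The model contract and the numpy backend

All methods are written against `ModelHandle`: forward evaluation, the
gradient of a target scalar with respect to the input or any named layer's
activation, and a guided-ReLU backward variant that leaves forward outputs
bit-identical.  The bundled backend is a small numpy/scipy layer stack
(same-padded convolution with odd kernels, ReLU, tanh, average pooling,
nearest-neighbour upsampling, global average pooling, channel mean, dense,
inert dropout) with hand-derived adjoints; convolution forward/backward are
exact adjoint pairs (`scipy.ndimage` correlate/convolve), so gradients are
exact to float precision.  Inference semantics throughout: dropout inert,
no stochastic layers.  Every backward path is validated against a
central-finite-difference oracle (step `1e-4`, relative tolerance `1e-3`
where the gradient exceeds `1e-6`) on all six registered fixture models.

## Preprocessing and I/O

* NIfTI (one 4D file or one file per modality) and PNG; float32 round-trip
  with the affine preserved.
* Per-modality z-score over the nonzero support (the brain, for
  skull-stripped data), `ε = 1e-8` guard, optional min–max rescale to [0,1]
  afterwards (off by default).  The support choice is exposed
  (`support="all"`); all-zero channels pass through with a warning.
* Center crop / symmetric zero-pad to the standard 192×224×160 grid, with
  the affine translated so retained voxels keep their world coordinates.
  Crop placement is the volume center (bounding-box cropping is a
  deliberate non-feature: it would make the output geometry depend on the
  segmentation).
* Seeded 128³ patch extraction.
* Rendering: grayscale magnitude maps (per-voxel max-|value| over channels,
  normalized at the 99th percentile — for sparse maps where that percentile
  is zero, the maximum is used instead) and red-dominant heat overlays with
  score-scaled opacity on an anatomical slice.

## Synthetic fixtures

The phantom generator emulates the statistical shape of multi-modal brain
MRI at desk scale, not its physics: an ellipsoidal brain (42% of each axis)
with smooth Gaussian-filtered background texture (σ = 2 voxels, 10%
amplitude), one ellipsoidal tumor blob of elevated intensity with
channel-specific contrast weights (0.6, 1.0, 0.8, 1.2 — the FLAIR-like
channel sees the lesion most), and a two-way grading label defined by blob
contrast (0.4 = low grade, 1.2 = high grade).  Default volumes are 32³
(tests) — real volumes are an order of magnitude larger per axis; nothing
in the code depends on size.  What passing tests show is that the
*machinery* is correct (gradients, path integrals, localization); they say
nothing about explanation quality on real MRI, which depends on the trained
model being explained.

Fixture models: a pure linear map (closed-form oracle for the path
methods); a hand-set blob detector (channel mean → box-average convolution
with bias −1.5 → ReLU → per-class heads) whose evidence map is analytically
the supra-threshold smoothed intensity, giving ground truth for Grad-CAM
localization; desk-scale ReLU classifier and encoder–decoder segmenter
stand-ins with named, inspectable layers; a transfer-learning classifier
head (2D average pool → flatten → dense 256 → dropout → dense 2, dropout
rate 0.5, pool size 2 — both configurable); and a small *tanh* CNN used for
path-integral convergence checks.  The smooth fixture exists because with
ReLU the path integrand is piecewise constant and the midpoint-rule error
is not guaranteed monotone in the step count; with a smooth nonlinearity it
decays at the textbook O(steps⁻²) rate, so the convergence property is
testable.  The classifier's final dense layer can be fitted by logistic
regression on the frozen convolutional features — sufficient for the
phantom grading dichotomy — rather than by a gradient training loop, which
the attribution framework does not need.

## Numerical choices and degenerate inputs

* Gradients are taken with respect to the preprocessed (z-scored) input —
  what the network actually consumes.
* IG/GIG baselines must be finite and shape-matched; `steps ≥ 1` enforced.
* GIG convergence test `|x_i − cur_i| ≤ 1e-9`; terminal float dust below
  `1e-6` of the initial gap is not reported as truncation.
* SmoothGrad with a constant input (`max = min`) degenerates to zero noise.
* Grad-CAM on an all-negative weighted sum returns the all-zero map (ReLU),
  rendered black with a warning.
* All stochastic components take explicit seeds; the CLI refuses unseeded
  SmoothGrad.

## Known limitations

* The backend covers the layer vocabulary of the fixture models; arbitrary
  architectures (residual connections, normalization layers, attention) are
  out of its scope, though any object implementing the backend protocol can
  stand behind a `ModelHandle`.
* GIG completeness is approximate on nonlinear models (typically a few
  percent at the 64-step default; the exact figure varies with the model
  and input).
* Layer inspection outputs maps only; assigning semantic concepts to layers
  is left to the reader.
* Phantoms are statistical stand-ins; no claim of clinical realism.
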