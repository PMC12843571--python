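# Methods note

## Model

The pipeline fuses a grayscale MRI plane and an RGB PET image into one RGB
image. PET is converted to BT.601 YUV (full-range, analog U/V scaling); its
chrominance is passed through to the output bit-for-bit, so all fusion
happens on luminance. Each luminance plane is split by an economy SVD into a
rank-k structural part `L_k = U Σ_k Vᵀ` and the residual `H = I − L_k`.
By the Eckart–Young theorem `L_k` is the best rank-k approximation in the
Frobenius norm, and the residual energy equals the sum of squared discarded
singular values — both identities are asserted in the tests.

Low frequencies are blended with energy-adaptive weights
`α = E_mri/(E_mri + E_pet)` (with `α = 0.5` and a warning when both energies
vanish). High frequencies are modulated by a single scalar gate
`½(μ_mri + μ_pet)` applied to the PET residual, where each `μ` is the global
mean activation of the deepest block of a convolutional feature extractor
evaluated on the min–max-rescaled residual. Fusion modes: `svd_vgg`
(default), `svd_only` (residuals discarded), `vgg_only` (whole-luminance
blend with feature-derived weights `μ_mri/(μ_mri + μ_pet)` — a design choice,
since a band split is unavailable in that mode), and `rgb_svd_vgg`
(per-RGB-channel ablation baseline).

## Feature extractor

The extractor is a VGG19-shaped stack of 3×3 convolutions with ReLU and 2×2
max pooling, implemented in numpy (im2col + BLAS for the forward pass,
explicit backward passes for training). Inputs are resized to 224×224,
replicated to 3 channels, and normalized as `(I − 0.5)/0.5`. Besides the
full `vgg19` width, a `small` width (4–32 channels) is provided for fast
experiments, plus a `stub` backbone (1×1 identity convolution, so `μ` is the
mean positive normalized intensity and hand-checkable) and a `zero` backbone.
Fine-tuning minimizes the L1 distance between the features of an image and a
randomly augmented copy (resize, horizontal flip p=0.5, rotation ±15°,
brightness/contrast ±0.2, Gaussian blur σ ∈ [0.1, 2]) with Adam at lr 1e-5,
a StepLR schedule (step 3, γ 0.7, so the rate drops to 0.7e-5 after epoch 3
and 0.49e-5 after epoch 6), and global gradient-norm clipping at 1.0. The
gradient flows through both branches of the loss.

## Noise model and denoising

MRI noise is additive Gaussian with headline variance σ² = 0.25 on the [0, 1]
scale (sweep values 0.01, 0.04, 0.09, 0.16, 0.25); the pre-clip field is kept
for variance bookkeeping, since clipping to [0, 1] biases the sample
variance. PET noise is Poisson: counts drawn at `I · peak` with default
peak 255 and rescaled, per RGB channel with per-channel seeds. Denoising uses
a bilateral filter for MRI (σ_s = 3 px, σ_r = 0.1, radius 5) and, for PET,
per-channel non-local means (h = 0.1, patch radius 3, search radius 10)
followed by a guided filter (radius 4, ε = 1e-4) guided by the NLM luminance.
All three filters are exact vectorized evaluations of their defining sums;
the tests compare them to independent double-loop implementations at 1e-12.

## Synthetic phantom

`make_phantom_pair` generates an elliptical "brain" MRI with sinusoidal
texture (sharp, high average gradient) and a PET image of smooth Gaussian
activity blobs rendered through a hot colormap (smooth, with non-trivial
chrominance), plus a reference proxy whose luminance is the mean of the two
modal luminances and whose chrominance is the PET's. The phantom reproduces
the *structural contrast* the pipeline exploits — sharp anatomical detail
versus smooth colorful function — and supports seeded, bit-reproducible
panels. It does **not** emulate scanner physics: no point-spread function,
partial-volume effects, attenuation, bias fields, Rician magnitude noise, or
anatomically realistic geometry. Conclusions drawn from it are about the
algorithmic behavior of the pipeline, not clinical performance.

## Numerical choices

- **Exact additivity.** After computing `H = I − L`, the low band is
  re-assigned as `L = I − H`, which makes `L + H == I` bit-exact (a two-sum
  identity); tests assert exact equality at every rank.
- **Padding.** All filters use symmetric edge padding (`np.pad` "symmetric").
- **Guided filter floor.** The variance denominator uses `var + ε` with an
  additional floor of 1e-12 to avoid division blow-ups on constant patches;
  the floor is exposed so the ε = 0 self-guidance identity can be tested.
- **Gate rescaling.** Signed HF residuals are min–max rescaled to [0, 1]
  before backbone normalization; residual ranges below 1e-12 (e.g. at full
  rank) map to zero, so the gate degenerates gracefully.
- **Metrics scale.** All metrics take MAX = 1 (intensities in [0, 1]);
  `PSNR = 10 log10(1/MSE)`, with an `inf` sentinel and a warning at MSE = 0.
  SSIM uses a Gaussian 11×11 window (σ = 1.5, truncate 3.5) with border crop
  and population covariances, matching the standard reference
  implementation to floating-point accuracy.
- **Clipping discipline.** Intermediate fusion quantities are never clipped;
  clipping to [0, 1] happens once, at the final RGB conversion.
- **YUV inversion.** The published rounded inverse (R = Y + 1.1401 V, etc.)
  bounds the round trip at about 5e-3; the YCbCr path uses the exact matrix
  inverse and round-trips at 1e-6.

## Problem sizes

The package's own defaults are a 256×256 working size for fusion, 224×224
network inputs, 20-seed phantom panels at 128×128 for evaluation sweeps, and
small-width backbones for panels and training smoke runs; the full VGG19
width is supported everywhere but is roughly 10× slower per image in this
pure-numpy implementation. These sizes were chosen as a balance between
statistical stability of the panel means and turnaround during development.

## Limitations

- The feature extractor is randomly initialized (or consistency-fine-tuned
  from scratch); no pretrained perceptual weights are bundled, so `μ` values
  and the perceptual distance are not comparable across differently seeded
  backbones.
- The HF gate is a single global scalar; it cannot favor detail locally.
- The phantom's reference proxy is a construction, not ground truth; metric
  values against it measure internal consistency, not clinical fidelity.
- The SVD split is global and axis-aligned; rotationally structured texture
  is spread across many singular vectors, so small k can blur diagonal
  detail more than horizontal/vertical detail.
- Registration is assumed: inputs must already be aligned and equal-sized
  (the CLI resizes both to the working size).
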