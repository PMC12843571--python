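# svdfuse

Hybrid SVD / deep-feature fusion of multimodal brain images (MRI + PET),
as a Python library with a command-line interface.

## Scientific problem

Anatomical MRI shows tissue structure at high spatial resolution but carries
no functional information; PET shows metabolic activity as a color map but is
smooth and low-resolution. Image fusion combines the two into a single color
image that keeps the MRI detail and the PET functional coloring, for visual
reading and downstream quantification. The practical obstacles are (a) noise —
Gaussian-distributed in MRI magnitude images, Poisson-distributed in PET
counts — and (b) choosing, pixel by pixel and band by band, how much of each
modality to keep.

## Core model

Work in a luminance/chrominance space. The PET image is converted with the
BT.601 YUV transform

```
Y =  0.299 R + 0.587 G + 0.114 B
U = -0.147 R - 0.289 G + 0.436 B
V =  0.615 R - 0.515 G - 0.100 B
```

and its chrominance (U, V) is carried through to the output untouched, so the
functional color is preserved exactly. The luminance planes are each split by
a truncated singular value decomposition,

```
I = U Σ Vᵀ,   L_k = U Σ_k Vᵀ,   H = I − L_k,
```

where the rank-k part `L_k` is the best rank-k approximation of the image in
the Frobenius norm (the smooth structural content) and the residual `H`
carries edges and fine texture. The two bands are fused with different rules:

- **Low frequency (energy-adaptive):** `L_f = α L_mri + β L_pet` with
  `α = E_mri / (E_mri + E_pet)`, `β = 1 − α`, where `E` is the sum of squared
  coefficients of each low-rank plane. The modality with more structural
  energy dominates.
- **High frequency (feature-gated):** `H_f = ½(μ_mri + μ_pet) · H_pet`, where
  each `μ` is the global mean activation of a deep convolutional feature
  extractor (a VGG19-shaped network, Algorithm 1 below) applied to the
  min–max-rescaled residual. Salient detail in either modality opens the
  gate.

The fused luminance `Y_f = L_f + H_f` is recombined with the PET chrominance
and inverted back to RGB. A consistency-trained feature extractor can be
produced with the included training loop (Adam, lr 1e-5, StepLR with step 3
and γ 0.7, global gradient-norm clipping at 1.0, L1 feature-consistency loss
between an image and its augmented copy).

Optional preprocessing implements the modality-specific noise model and
denoisers: additive Gaussian noise / bilateral filtering for MRI, Poisson
noise / non-local means followed by guided filtering for PET. Quality is
assessed with entropy, standard deviation, average gradient, MSE, PSNR, SSIM,
correlation coefficient, and a learned perceptual distance, all on the [0, 1]
intensity scale.

## Worked example

```python
import svdfuse as sf

pair = sf.make_phantom_pair(seed=7, size=128)            # synthetic MRI/PET pair
cfg = sf.FusionConfig(backbone="small", working_size=128, k=20)
result = sf.fuse_pair(pair.mri, pair.pet, cfg)
report = sf.evaluate(result, reference=pair.gt_proxy)

print(f"alpha (MRI low-frequency weight) = {result.weights.alpha:.4f}")
print(f"HF gate (mu_mri, mu_pet) = ({result.gate.mu_mri:.4f}, {result.gate.mu_pet:.4f})")
for name, val in report.to_dict().items():
    if val is not None:
        print(f"{name:>5s} = {val:.4f}")
```

Output:

```
alpha (MRI low-frequency weight) = 0.6798
HF gate (mu_mri, mu_pet) = (0.0924, 0.0467)
   en = 5.4877
   sd = 0.2615
   ag = 0.0219
  mse = 0.0028
 psnr = 25.5106
 ssim = 0.9051
   cc = 0.9851
```

The sharper MRI phantom receives the larger low-frequency weight
(α ≈ 0.68), and its residual drives the larger half of the gate. With the
default `k=None` (full rank) the entire image lives in the low-frequency
band and the residual is zero to rounding; choose a finite `k` to engage the
high-frequency path.

The same run from the command line:

```
svdfuse phantom --seed 7 --size 128 --out-dir data/
svdfuse fuse --mri data/mri.png --pet data/pet.png --config cfg.yaml \
             --out fused.png --report report.csv --ref data/gt.png
svdfuse ablate-rank --k 10,20,50,full data/mri.png data/pet.png ranks.csv
```

Every CLI command writes a `.run.json` sidecar with the seed, configuration
and library versions used.

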