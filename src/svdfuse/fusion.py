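"""Energy-adaptive / feature-gated MRI-PET fusion.

The luminance planes of both modalities are split by SVD into low-frequency
structure L and high-frequency detail H.  Low frequencies are blended with
weights proportional to each modality's LF energy,

    alpha = E_mri / (E_mri + E_pet),   L_f = alpha L_mri + (1 - alpha) L_pet,

high frequencies are modulated by a single scalar gate derived from deep
feature activations,

    H_f = ((mu_mri + mu_pet) / 2) * H_pet,

and the fused luminance Y_f = L_f + H_f is recombined with the PET
chrominance planes, which pass through the pipeline bit-exactly.  Clipping
is deferred to the final RGB conversion so Y_f = L_f + H_f holds exactly
internally.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from skimage.transform import resize

from . import colorspace as cs
from .colorspace import RGBImage, YUVImage
from .decomposition import svd_decompose
from .denoise import BilateralParams, GuidedParams, NLMParams, denoise_mri, denoise_pet
from .features import ConvBackbone, FeatureGate, gate_from_hf, make_backbone
from .noise import NoiseSpec, apply_noise

__all__ = [
    "FusionWeights",
    "FusionConfig",
    "FusedResult",
    "fuse_lf",
    "fuse_hf",
    "reconstruct",
    "fuse_pair",
    "fuse_rgb_mode",
]

MODES = ("svd_vgg", "svd_only", "vgg_only", "rgb_svd_vgg")
COLOR_SPACES = ("yuv", "ycbcr")


@dataclass(frozen=True)
class FusionWeights:
    """LF energies and the adaptive blend weights derived from them."""

    e_mri: float
    e_pet: float
    alpha: float
    beta: float


@dataclass(frozen=True)
class FusionConfig:
    """All pipeline knobs.

    ``k=None`` means full-rank SVD (the default operating point).  Noise and
    denoising stages are disabled by default so clean-input runs are the
    baseline; enable them to emulate degraded acquisitions.
    """

    mode: str = "svd_vgg"
    color_space: str = "yuv"
    k: Optional[int] = None
    working_size: int = 256
    seed: int = 0
    backbone: str = "vgg19"
    feature_block: Optional[int] = None  # None = deepest conv block
    mri_noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(kind="none"))
    pet_noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(kind="none"))
    denoise: bool = False
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    nlm: NLMParams = field(default_factory=NLMParams)
    guided: GuidedParams = field(default_factory=GuidedParams)
    denoise_before_colorspace: bool = True
    hf_blend: float = 0.0  # optional MRI HF admixture; 0 = as published
    use_printed_yuv_matrix: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.color_space not in COLOR_SPACES:
            raise ValueError(f"color_space must be one of {COLOR_SPACES}, got {self.color_space!r}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1 or None for full rank")
        if self.working_size < 8:
            raise ValueError("working_size too small")

    def with_rank(self, k: Optional[int]) -> "FusionConfig":
        return replace(self, k=k)

    def make_extractor(self) -> ConvBackbone:
        return make_backbone(self.backbone, seed=self.seed)


@dataclass(frozen=True)
class FusedResult:
    fused_rgb: RGBImage
    y_fused: np.ndarray
    l_fused: np.ndarray
    h_fused: np.ndarray
    weights: FusionWeights
    gate: Optional[FeatureGate]
    provenance: dict


def fuse_lf(l_mri: np.ndarray, l_pet: np.ndarray) -> tuple[np.ndarray, FusionWeights]:
    """Energy-adaptive low-frequency blend.

    The degenerate case of two zero-energy planes falls back to an equal
    blend (alpha = 0.5) with a warning.
    """
    l_mri = np.asarray(l_mri, dtype=float)
    l_pet = np.asarray(l_pet, dtype=float)
    if l_mri.shape != l_pet.shape:
        raise ValueError("LF planes must share a shape")
    e_mri = float(np.sum(l_mri**2))
    e_pet = float(np.sum(l_pet**2))
    total = e_mri + e_pet
    if total > 0:
        alpha = e_mri / total
    else:
        warnings.warn("both LF energies are zero; using alpha = 0.5", stacklevel=2)
        alpha = 0.5
    beta = 1.0 - alpha
    fused = alpha * l_mri + beta * l_pet
    return fused, FusionWeights(e_mri=e_mri, e_pet=e_pet, alpha=alpha, beta=beta)


def fuse_hf(h_mri: np.ndarray, h_pet: np.ndarray, gate: FeatureGate) -> np.ndarray:
    """Scalar-gated high-frequency fusion: H_f = gate * H_pet.

    The MRI high-frequency map contributes only through its mean activation
    mu inside the gate; its spatial content is deliberately not mixed in.
    """
    h_pet = np.asarray(h_pet, dtype=float)
    g = gate.gate
    if not np.isfinite(g):
        raise FloatingPointError("non-finite fusion gate")
    return g * h_pet


def reconstruct(l_f: np.ndarray, h_f: np.ndarray, u: np.ndarray, v: np.ndarray,
                color_space: str = "yuv") -> tuple[RGBImage, np.ndarray]:
    """Y_f = L_f + H_f, recombined with the PET chrominance planes.

    Returns ``(rgb, y_fused)``; values are clipped only inside the final RGB
    conversion, so the returned luminance is the exact pre-clip sum.
    """
    y_f = np.asarray(l_f, dtype=float) + np.asarray(h_f, dtype=float)
    yuv = YUVImage(y_f, np.asarray(u, dtype=float), np.asarray(v, dtype=float))
    rgb = cs.yuv_to_rgb(yuv) if color_space == "yuv" else cs.ycbcr_to_rgb(yuv)
    return rgb, y_f


def _to_working(img: np.ndarray, size: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, mode="reflect", anti_aliasing=False)
    return np.clip(img, 0.0, 1.0)


def _rgb_to_working(img: RGBImage, size: int) -> RGBImage:
    if img.shape == (size, size):
        return img
    return RGBImage(
        _to_working(img.r, size), _to_working(img.g, size), _to_working(img.b, size)
    )


def _prepare_inputs(mri: np.ndarray, pet: RGBImage, cfg: FusionConfig):
    """Resize -> noise -> denoise, per the configured degradation stages."""
    mri = _to_working(mri, cfg.working_size)
    if not isinstance(pet, RGBImage):
        pet = RGBImage.from_array(pet)
    pet = _rgb_to_working(pet, cfg.working_size)
    mri = apply_noise(mri, cfg.mri_noise)
    pet = apply_noise(pet, cfg.pet_noise)
    if cfg.denoise:
        mri = denoise_mri(mri, cfg.bilateral)
        pet = denoise_pet(pet, cfg.nlm, cfg.guided)
    return mri, pet


def _split_pet(pet: RGBImage, cfg: FusionConfig) -> YUVImage:
    if cfg.color_space == "yuv":
        return cs.rgb_to_yuv(pet, use_printed_matrix=cfg.use_printed_yuv_matrix)
    return cs.rgb_to_ycbcr(pet)


def fuse_pair(mri: np.ndarray, pet: RGBImage, cfg: FusionConfig = FusionConfig(),
              extractor: ConvBackbone | None = None) -> FusedResult:
    """End-to-end fusion of one MRI/PET pair.

    Steps: optional degradation/denoising, PET color-space split, SVD of both
    luminance planes at the configured rank, energy-adaptive LF fusion,
    feature-gated HF fusion, luminance reconstruction and chrominance
    reattachment.  Deterministic for a fixed config (all randomness flows
    from ``cfg.seed``).  A pre-built ``extractor`` may be passed to avoid
    re-initializing the backbone.
    """
    if cfg.mode == "rgb_svd_vgg":
        return fuse_rgb_mode(mri, pet, cfg, extractor)
    mri_p, pet_p = _prepare_inputs(mri, pet, cfg)
    pet_yuv = _split_pet(pet_p, cfg)
    y_mri, y_pet = mri_p, pet_yuv.y

    if cfg.mode == "vgg_only":
        # no SVD decomposition or energy weighting: the whole luminance
        # planes are blended with weights proportional to their feature
        # activations
        if extractor is None:
            extractor = cfg.make_extractor()
        gate = gate_from_hf(extractor, y_mri, y_pet, cfg.feature_block)
        mu_sum = gate.mu_mri + gate.mu_pet
        w_mri = 0.5 if mu_sum == 0 else gate.mu_mri / mu_sum
        l_f = w_mri * y_mri + (1.0 - w_mri) * y_pet
        h_f = np.zeros_like(l_f)
        weights = FusionWeights(e_mri=float(np.sum(y_mri**2)), e_pet=float(np.sum(y_pet**2)),
                                alpha=w_mri, beta=1.0 - w_mri)
    else:
        dec_mri = svd_decompose(y_mri, cfg.k)
        dec_pet = svd_decompose(y_pet, cfg.k)
        l_f, weights = fuse_lf(dec_mri.low, dec_pet.low)
        if cfg.mode == "svd_only":
            gate = None
            h_f = np.zeros_like(l_f)
        else:
            if extractor is None:
                extractor = cfg.make_extractor()
            gate = gate_from_hf(extractor, dec_mri.high, dec_pet.high, cfg.feature_block)
            h_f = fuse_hf(dec_mri.high, dec_pet.high, gate)
            if cfg.hf_blend:
                h_f = h_f + cfg.hf_blend * dec_mri.high

    rgb, y_f = reconstruct(l_f, h_f, pet_yuv.u, pet_yuv.v, cfg.color_space)
    provenance = {
        "config": cfg,
        "mri_luminance": y_mri,
        "pet_luminance": y_pet,
        "pet_u": pet_yuv.u,
        "pet_v": pet_yuv.v,
    }
    return FusedResult(fused_rgb=rgb, y_fused=y_f, l_fused=l_f, h_fused=h_f,
                       weights=weights, gate=gate, provenance=provenance)


def fuse_rgb_mode(mri: np.ndarray, pet: RGBImage, cfg: FusionConfig = FusionConfig(mode="rgb_svd_vgg"),
                  extractor: ConvBackbone | None = None) -> FusedResult:
    """Ablation baseline: per-channel SVD + gated fusion directly in RGB.

    The grayscale MRI is replicated across R, G, B and each channel pair is
    fused independently with the same LF/HF rules; no chrominance separation
    takes place.
    """
    mri_p, pet_p = _prepare_inputs(mri, pet, cfg)
    if extractor is None:
        extractor = cfg.make_extractor()
    fused_channels = []
    weights = gate = None
    for chan in (pet_p.r, pet_p.g, pet_p.b):
        dec_mri = svd_decompose(mri_p, cfg.k)
        dec_pet = svd_decompose(chan, cfg.k)
        l_f, w = fuse_lf(dec_mri.low, dec_pet.low)
        g = gate_from_hf(extractor, dec_mri.high, dec_pet.high, cfg.feature_block)
        h_f = fuse_hf(dec_mri.high, dec_pet.high, g)
        fused_channels.append(l_f + h_f)
        if weights is None:
            weights, gate = w, g
    y_f = (0.299 * fused_channels[0] + 0.587 * fused_channels[1] + 0.114 * fused_channels[2])
    rgb = RGBImage(*fused_channels)
    provenance = {"config": cfg, "mri_luminance": mri_p, "pet_luminance": pet_p.luminance()}
    return FusedResult(fused_rgb=rgb, y_fused=y_f, l_fused=y_f, h_fused=np.zeros_like(y_f),
                       weights=weights, gate=gate, provenance=provenance)
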