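"""Hybrid edge-preserving denoising.

The MRI plane is cleaned with a bilateral filter (spatial x range Gaussian
weights); the PET image with a two-phase chain of non-local means followed by
guided filtering, the guide being the luminance of the NLM output.  All three
filters are direct, exact evaluations of their defining formulas (vectorized
over window offsets), so they agree with brute-force per-pixel loops to
floating-point precision.  Borders use symmetric (edge-repeat) padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .colorspace import RGBImage

__all__ = [
    "BilateralParams",
    "NLMParams",
    "GuidedParams",
    "bilateral",
    "nlm",
    "guided_filter",
    "denoise_mri",
    "denoise_pet",
]

_PAD_MODE = "symmetric"  # np.pad name; scipy equivalent is mode="reflect"


@dataclass(frozen=True)
class BilateralParams:
    sigma_s: float = 3.0  # spatial scale, pixels
    sigma_r: float = 0.1  # range scale, intensity units
    radius: int = 5  # half-window

    def __post_init__(self):
        if self.sigma_s <= 0 or self.sigma_r <= 0 or self.radius <= 0:
            raise ValueError("bilateral parameters must be positive")


@dataclass(frozen=True)
class NLMParams:
    h: float = 0.1  # filtering strength, intensity units
    patch_radius: int = 3
    search_radius: int = 10

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.patch_radius > self.search_radius:
            raise ValueError("patch_radius must be <= search_radius")


@dataclass(frozen=True)
class GuidedParams:
    radius: int = 4  # box-window half-size
    eps: float = 1e-4  # regularizer, intensity^2 units
    var_floor: float = 1e-12  # guards 0/0 on constant windows

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


def bilateral(img: np.ndarray, p: BilateralParams = BilateralParams()) -> np.ndarray:
    """Edge-preserving smoothing.

    Each output pixel is the normalized sum over the (2r+1)^2 window of
    neighbors weighted by exp(-d^2 / 2 sigma_s^2) * exp(-(I(x)-I(i))^2 /
    2 sigma_r^2).
    """
    img = np.asarray(img, dtype=float)
    r = p.radius
    padded = np.pad(img, r, mode=_PAD_MODE)
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    h, w = img.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            ws = np.exp(-(dy * dy + dx * dx) / (2.0 * p.sigma_s**2))
            wr = np.exp(-((img - shifted) ** 2) / (2.0 * p.sigma_r**2))
            weight = ws * wr
            num += weight * shifted
            den += weight
    return num / den


def nlm(img: np.ndarray, p: NLMParams = NLMParams()) -> np.ndarray:
    """Non-local means.

    Weights w(x, i) = exp(-||P_x - P_i||^2 / h^2) / Z(x) with P the
    (2 patch_radius + 1)^2 patch and the sum running over the search window
    (self term included).
    """
    img = np.asarray(img, dtype=float)
    pr, sr = p.patch_radius, p.search_radius
    h2 = p.h * p.h
    hgt, wid = img.shape
    pad = pr + sr
    padded = np.pad(img, pad, mode=_PAD_MODE)
    center = padded[sr:-sr or None, sr:-sr or None]  # img padded by pr only
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    psize = 2 * pr + 1
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            shifted = padded[pad + dy - pr : pad + dy + pr + hgt, pad + dx - pr : pad + dx + pr + wid]
            diff2 = (center - shifted) ** 2
            # sum of squared patch differences per pixel, via a box sum
            ssd = ndi.uniform_filter(diff2, size=psize, mode="constant")[pr : pr + hgt, pr : pr + wid] * psize**2
            weight = np.exp(-ssd / h2)
            num += weight * shifted[pr : pr + hgt, pr : pr + wid]
            den += weight
    return num / den


def _box_mean(img: np.ndarray, radius: int) -> np.ndarray:
    return ndi.uniform_filter(img, size=2 * radius + 1, mode="reflect")


def guided_filter(p_img: np.ndarray, guide: np.ndarray, gp: GuidedParams = GuidedParams()) -> np.ndarray:
    """Guided filter: per-window linear model q = a * I + b.

    a_k = cov(I, p) / (var(I) + eps), b_k = mean(p) - a_k mean(I), with the
    coefficients averaged over all windows covering each pixel.
    """
    p_img = np.asarray(p_img, dtype=float)
    guide = np.asarray(guide, dtype=float)
    if p_img.shape != guide.shape:
        raise ValueError("input and guide must share a shape")
    r = gp.radius
    mean_i = _box_mean(guide, r)
    mean_p = _box_mean(p_img, r)
    corr_ii = _box_mean(guide * guide, r)
    corr_ip = _box_mean(guide * p_img, r)
    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + gp.eps + gp.var_floor)
    b = mean_p - a * mean_i
    return _box_mean(a, r) * guide + _box_mean(b, r)


def denoise_mri(img: np.ndarray, p: BilateralParams = BilateralParams()) -> np.ndarray:
    """Bilateral filtering with MRI defaults; output clipped to [0, 1]."""
    return np.clip(bilateral(img, p), 0.0, 1.0)


def denoise_pet(
    img: RGBImage,
    nlm_p: NLMParams = NLMParams(),
    g_p: GuidedParams = GuidedParams(),
) -> RGBImage:
    """Two-phase PET denoising: per-channel NLM, then guided filtering.

    The guide is the luminance of the NLM output, so chroma channels inherit
    edge structure from the already-smoothed intensity.
    """
    phase1 = RGBImage(nlm(img.r, nlm_p), nlm(img.g, nlm_p), nlm(img.b, nlm_p))
    guide = phase1.luminance()
    return RGBImage(
        np.clip(guided_filter(phase1.r, guide, g_p), 0.0, 1.0),
        np.clip(guided_filter(phase1.g, guide, g_p), 0.0, 1.0),
        np.clip(guided_filter(phase1.b, guide, g_p), 0.0, 1.0),
    )
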