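"""Fusion quality metrics.

No-reference measures (entropy, standard deviation, average gradient) are
computed on the fused luminance; reference-based measures (MSE, PSNR, SSIM,
Pearson correlation) compare luminance planes against a ground-truth fused
image.  The perceptual distance compares deep feature maps of RGB images
layer by layer (channel-weighted squared differences, spatially averaged and
summed over layers) through a pluggable convolutional backend.

All images are on the [0, 1] scale; MAX = 1 throughout, so PSNR and MSE obey
PSNR = 10 log10(1 / MSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .colorspace import RGBImage

__all__ = [
    "MetricsReport",
    "entropy",
    "std_dev",
    "avg_gradient",
    "mse",
    "psnr",
    "ssim",
    "cc",
    "PerceptualBackend",
    "perceptual_distance",
    "evaluate",
]

MAX_VAL = 1.0


def entropy(img: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram.

    256 equal bins on [0, 1]; empty bins contribute 0 (0 log 0 := 0).
    """
    img = np.asarray(img, dtype=float)
    hist, _ = np.histogram(img, bins=bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def std_dev(img: np.ndarray) -> float:
    """Population standard deviation about the image mean (1/MN normalizer)."""
    img = np.asarray(img, dtype=float)
    return float(np.sqrt(np.mean((img - img.mean()) ** 2)))


def avg_gradient(img: np.ndarray) -> float:
    """Mean local gradient magnitude sqrt((dx^2 + dy^2) / 2) over the
    (M-1) x (N-1) forward-difference grid."""
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2 x 2")
    dx = img[1:, :-1] - img[:-1, :-1]
    dy = img[:-1, 1:] - img[:-1, :-1]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


def mse(ref: np.ndarray, img: np.ndarray) -> float:
    ref = np.asarray(ref, dtype=float)
    img = np.asarray(img, dtype=float)
    if ref.shape != img.shape:
        raise ValueError("images must share a shape")
    return float(np.mean((ref - img) ** 2))


def psnr(ref: np.ndarray, img: np.ndarray, max_val: float = MAX_VAL) -> float:
    """10 log10(MAX^2 / MSE) in dB; identical images yield +inf with a warning."""
    err = mse(ref, img)
    if err == 0:
        warnings.warn("MSE is zero; PSNR is unbounded", stacklevel=2)
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / err))


def _gaussian_filter(img: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    return ndi.gaussian_filter(img, sigma, truncate=truncate, mode="reflect")


def ssim(ref: np.ndarray, img: np.ndarray, max_val: float = MAX_VAL,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local structural similarity.

    Gaussian window (sigma 1.5 truncated at 3.5 sigma -> 11 x 11),
    C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2; the window-radius border is
    excluded from the average.
    """
    x = np.asarray(ref, dtype=float)
    y = np.asarray(img, dtype=float)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    truncate = 3.5
    radius = int(truncate * sigma + 0.5)
    c1 = (k1 * max_val) ** 2
    c2 = (k2 * max_val) ** 2
    ux = _gaussian_filter(x, sigma, truncate)
    uy = _gaussian_filter(y, sigma, truncate)
    uxx = _gaussian_filter(x * x, sigma, truncate)
    uyy = _gaussian_filter(y * y, sigma, truncate)
    uxy = _gaussian_filter(x * y, sigma, truncate)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    core = s[radius:-radius, radius:-radius]
    return float(core.mean())


def cc(ref: np.ndarray, img: np.ndarray) -> float:
    """Pearson correlation over all pixels; undefined for constant images."""
    ref = np.asarray(ref, dtype=float)
    img = np.asarray(img, dtype=float)
    if ref.shape != img.shape:
        raise ValueError("images must share a shape")
    r = ref - ref.mean()
    f = img - img.mean()
    sr = np.sqrt(np.mean(r**2))
    sf = np.sqrt(np.mean(f**2))
    if sr == 0 or sf == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.mean(r * f) / (sr * sf))


class PerceptualBackend:
    """Deep-feature distance backend built on a convolutional backbone.

    Feature vectors are unit-normalized along the channel axis at every
    spatial position; squared differences are channel-weighted (uniform 1/C
    by default), spatially averaged, and summed over the block outputs.
    """

    def __init__(self, extractor=None, seed: int = 0):
        if extractor is None:
            from .features import make_backbone

            extractor = make_backbone("small", seed=seed)
        self.extractor = extractor

    def _feats(self, img: RGBImage):
        from skimage.transform import resize

        from .features import INPUT_SIZE

        arr = img.to_array()
        if arr.shape[:2] != (INPUT_SIZE, INPUT_SIZE):
            arr = resize(arr, (INPUT_SIZE, INPUT_SIZE), order=1, mode="reflect", anti_aliasing=False)
        x = ((arr - 0.5) / 0.5).transpose(2, 0, 1).astype(np.float32)
        return self.extractor.forward(x, collect=True)

    def distance(self, img1: RGBImage, img2: RGBImage) -> float:
        f1s = self._feats(img1)
        f2s = self._feats(img2)
        total = 0.0
        for f1, f2 in zip(f1s, f2s):
            n1 = f1 / (np.linalg.norm(f1, axis=0, keepdims=True) + 1e-10)
            n2 = f2 / (np.linalg.norm(f2, axis=0, keepdims=True) + 1e-10)
            diff2 = (n1 - n2) ** 2
            total += float(diff2.mean(axis=(1, 2)).sum() / f1.shape[0])
        return total


def perceptual_distance(img1: RGBImage, img2: RGBImage,
                        backend: Optional[PerceptualBackend] = None) -> float:
    """Perceptual feature distance between two RGB images (lower = closer).

    With no backend supplied, a seeded default backend is constructed.
    """
    if backend is None:
        backend = PerceptualBackend()
    return backend.distance(img1, img2)


@dataclass(frozen=True)
class MetricsReport:
    en: float
    sd: float
    ag: float
    mse: Optional[float] = None
    psnr: Optional[float] = None
    ssim: Optional[float] = None
    cc: Optional[float] = None
    lpips_ref: Optional[float] = None
    lpips_pet: Optional[float] = None
    lpips_mri: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def evaluate(fused, reference: Optional[RGBImage] = None,
             pet: Optional[RGBImage] = None, mri: Optional[np.ndarray] = None,
             perceptual: Optional[PerceptualBackend] = None) -> MetricsReport:
    """Assemble a full metrics report for a fusion result.

    EN/SD/AG are computed on the fused luminance; MSE/PSNR/SSIM/CC against
    the reference luminance when a reference is given.  Perceptual distances
    (fused vs reference / PET / MRI) are filled only when a backend is
    supplied; a missing backend downgrades to a warning, never an error.
    """
    fused_rgb = fused.fused_rgb if hasattr(fused, "fused_rgb") else fused
    lum = fused_rgb.luminance()
    fields = {"en": entropy(lum), "sd": std_dev(lum), "ag": avg_gradient(lum)}
    if reference is not None:
        ref_lum = reference.luminance()
        fields["mse"] = mse(ref_lum, lum)
        fields["psnr"] = psnr(ref_lum, lum)
        fields["ssim"] = ssim(ref_lum, lum)
        fields["cc"] = cc(ref_lum, lum)
    if perceptual is not None:
        if reference is not None:
            fields["lpips_ref"] = perceptual.distance(fused_rgb, reference)
        if pet is not None:
            fields["lpips_pet"] = perceptual.distance(fused_rgb, pet)
        if mri is not None:
            mri_arr = np.asarray(mri, dtype=float)
            fields["lpips_mri"] = perceptual.distance(fused_rgb, RGBImage(mri_arr, mri_arr, mri_arr))
    elif pet is not None or mri is not None:
        warnings.warn("no perceptual backend available; perceptual metrics omitted", stacklevel=2)
    return MetricsReport(**fields)
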