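"""Synthetic modality-specific degradation.

MRI acquisitions are modelled with additive zero-mean Gaussian noise of
variance ``sigma2`` (intensity^2 units on the [0, 1] scale); PET with Poisson
photon noise, where ``peak`` sets the photon budget at full intensity
(noisy = Poisson(I * peak) / peak).  Everything is driven by explicit integer
seeds so degraded inputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .colorspace import RGBImage

__all__ = ["NoiseSpec", "add_gaussian", "add_poisson", "apply_noise", "noise_sweep"]

#: variance sweep used for noise-sensitivity analysis
SIGMA2_SWEEP = (0.01, 0.04, 0.09, 0.16, 0.25)


@dataclass(frozen=True)
class NoiseSpec:
    """Degradation recipe for one modality."""

    kind: str = "none"  # gaussian | poisson | none
    sigma2: float = 0.25
    peak: float = 255.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.peak <= 0:
            raise ValueError("peak must be > 0")


def add_gaussian(img: np.ndarray, sigma2: float, seed: int, *, clip: bool = True) -> np.ndarray:
    """Add i.i.d. N(0, sigma2) per pixel.

    ``clip=False`` returns the pre-clip field, which is what variance
    bookkeeping should be done on (clipping biases the sample variance).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    img = np.asarray(img, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = img + rng.normal(0.0, np.sqrt(sigma2), size=img.shape)
    return np.clip(noisy, 0.0, 1.0) if clip else noisy


def add_poisson(img: np.ndarray, peak: float, seed: int) -> np.ndarray:
    """Poisson photon noise: Poisson(I * peak) / peak, clipped to [0, 1]."""
    if peak <= 0:
        raise ValueError("peak must be > 0")
    img = np.asarray(img, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(np.clip(img, 0.0, 1.0) * peak).astype(float) / peak
    return np.clip(noisy, 0.0, 1.0)


def apply_noise(img, spec: NoiseSpec):
    """Apply a NoiseSpec to a grayscale plane or an RGBImage.

    Poisson noise on RGB is drawn independently per channel (separate photon
    streams per displayed channel); Gaussian noise likewise.
    """
    if spec.kind == "none":
        return img
    if isinstance(img, RGBImage):
        planes = []
        for i, plane in enumerate((img.r, img.g, img.b)):
            if spec.kind == "gaussian":
                planes.append(add_gaussian(plane, spec.sigma2, spec.seed + i))
            else:
                planes.append(add_poisson(plane, spec.peak, spec.seed + i))
        return RGBImage(*planes)
    if spec.kind == "gaussian":
        return add_gaussian(img, spec.sigma2, spec.seed)
    return add_poisson(img, spec.peak, spec.seed)


def noise_sweep(
    mri: np.ndarray,
    pet: RGBImage,
    sigma2_list: Sequence[float],
    peak: float = 255.0,
    seed: int = 0,
):
    """Degrade an (MRI, PET) pair at several Gaussian variances.

    The PET degradation is drawn once (same seed) and shared across entries,
    so the sweep isolates the effect of the MRI noise level.
    """
    sigma2_list = list(sigma2_list)
    if not sigma2_list:
        raise ValueError("sigma2_list must be non-empty")
    noisy_pet = apply_noise(pet, NoiseSpec(kind="poisson", peak=peak, seed=seed))
    out = []
    for s2 in sigma2_list:
        noisy_mri = mri if s2 == 0 else add_gaussian(mri, s2, seed)
        out.append((noisy_mri, noisy_pet))
    return out
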