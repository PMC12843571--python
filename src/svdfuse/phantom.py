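"""Seeded phantom MRI/PET pairs for pipeline exercise.

The MRI phantom is piecewise smooth with sharp boundaries and fine texture
(nested ellipses standing in for skull/brain/ventricles, plus a low-amplitude
sinusoidal grain), matching the structural role of anatomical imaging.  The
PET phantom is a set of smooth "metabolic" blobs rendered through a
hot-style colormap, so its chrominance planes are non-trivial and its
luminance is low-frequency.  A deterministic ground-truth proxy (blended
luminance + PET chrominance) enables reference-based metric plumbing; it is
an internal construction, not a clinical ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .colorspace import RGBImage, YUVImage, rgb_to_yuv, yuv_to_rgb

__all__ = ["PhantomPair", "make_phantom_pair", "make_rank_r_image"]


@dataclass(frozen=True)
class PhantomPair:
    mri: np.ndarray
    pet: RGBImage
    gt_proxy: RGBImage
    params: dict


def _grid(size: int):
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return (y - c) / c, (x - c) / c


def _ellipse(yy, xx, cy, cx, ry, rx, angle):
    ca, sa = np.cos(angle), np.sin(angle)
    yr = (yy - cy) * ca + (xx - cx) * sa
    xr = -(yy - cy) * sa + (xx - cx) * ca
    return (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0


def _hot_colormap(t: np.ndarray) -> RGBImage:
    """Hot-style map: black -> red -> yellow -> white as t goes 0 -> 1."""
    r = np.clip(3.0 * t, 0.0, 1.0)
    g = np.clip(3.0 * t - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * t - 2.0, 0.0, 1.0)
    return RGBImage(r, g, b)


def make_phantom_pair(seed: int, size: int = 256) -> PhantomPair:
    """Generate one deterministic MRI/PET phantom pair.

    The MRI carries sharp edges and fine sinusoidal texture; the PET
    luminance is smooth and its chrominance is guaranteed non-trivial
    (max |u| > 0.05 by construction of the hot colormap).
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    yy, xx = _grid(size)

    # --- MRI: nested ellipses with sharp boundaries
    mri = np.zeros((size, size))
    mri[_ellipse(yy, xx, 0.0, 0.0, 0.92, 0.8, 0.0)] = 0.25  # skull interior
    mri[_ellipse(yy, xx, 0.0, 0.0, 0.82, 0.7, 0.0)] = 0.65  # brain tissue
    for _ in range(4):
        cy, cx = rng.uniform(-0.4, 0.4, size=2)
        ry, rx = rng.uniform(0.08, 0.25, size=2)
        level = rng.uniform(0.35, 0.95)
        mri[_ellipse(yy, xx, cy, cx, ry, rx, rng.uniform(0, np.pi))] = level
    mri[_ellipse(yy, xx, 0.05, -0.12, 0.18, 0.08, 0.3)] = 0.1  # ventricle
    mri[_ellipse(yy, xx, 0.05, 0.12, 0.18, 0.08, -0.3)] = 0.1
    # fine sinusoidal grain confined to tissue
    fy, fx = rng.uniform(18, 30, size=2)
    phase = rng.uniform(0, 2 * np.pi)
    texture = 0.05 * np.sin(fy * np.pi * yy + fx * np.pi * xx + phase)
    mri = np.clip(mri + texture * (mri > 0.2), 0.0, 1.0)

    # --- PET: smooth metabolic blobs through a hot colormap
    activity = np.zeros((size, size))
    for _ in range(5):
        cy, cx = rng.uniform(-0.55, 0.55, size=2)
        s = rng.uniform(0.12, 0.3)
        amp = rng.uniform(0.5, 1.0)
        activity += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    activity = ndi.gaussian_filter(activity, sigma=size / 64, mode="reflect")
    activity = activity / activity.max()
    activity *= _ellipse(yy, xx, 0.0, 0.0, 0.9, 0.78, 0.0)
    pet = _hot_colormap(activity)

    # --- ground-truth proxy: blended luminance + PET chrominance
    pet_yuv = rgb_to_yuv(pet)
    gt_lum = 0.5 * (mri + pet_yuv.y)
    gt_proxy = yuv_to_rgb(YUVImage(gt_lum, pet_yuv.u, pet_yuv.v))

    params = {"seed": seed, "size": size}
    return PhantomPair(mri=mri, pet=pet, gt_proxy=gt_proxy, params=params)


def make_rank_r_image(r: int, size: int, seed: int) -> np.ndarray:
    """Image of exact numerical rank ``r``: a non-negative sum of r outer
    products scaled into [0, 1] (pure scaling preserves the rank)."""
    if not 1 <= r <= size:
        raise ValueError(f"r must be in [1, {size}]")
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size))
    for _ in range(r):
        u = rng.random(size)
        v = rng.random(size)
        img += np.outer(u, v)
    return img / img.max()
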