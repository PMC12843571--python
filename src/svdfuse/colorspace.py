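"""RGB <-> YUV / YCbCr conversions on float planes.

Structural fusion runs on the luminance (Y) plane only; PET chrominance
(U, V or Cb, Cr) is carried through the pipeline untouched so the metabolic
color map survives fusion.  All conversions are plain per-pixel linear maps
on images normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RGBImage",
    "YUVImage",
    "rgb_to_yuv",
    "yuv_to_rgb",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
    "YUV_FORWARD",
    "YUV_FORWARD_PRINTED",
    "YUV_INVERSE",
]

# BT.601 luma weights with full-swing chroma (U in [-0.436, 0.436],
# V in [-0.615, 0.615]).  Row 3 uses the standard coefficient -0.515; a
# variant with -0.1515 (which destroys the gray axis) circulates in some
# write-ups and is kept available for comparison as YUV_FORWARD_PRINTED.
YUV_FORWARD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.147, -0.289, 0.436],
        [0.615, -0.515, -0.100],
    ]
)

YUV_FORWARD_PRINTED = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.147, -0.289, 0.436],
        [0.615, -0.1515, -0.100],
    ]
)

# Companion inverse: R = Y + 1.1401 V, G = Y - 0.395 U - 0.581 V,
# B = Y + 2.032 U.  Not the exact matrix inverse of YUV_FORWARD (the
# coefficients are rounded), so round-trips carry an O(1e-3) error.
YUV_INVERSE = np.array(
    [
        [1.0, 0.0, 1.1401],
        [1.0, -0.395, -0.581],
        [1.0, 2.032, 0.0],
    ]
)

# Full-range BT.601 YCbCr; the inverse is computed exactly so the pair
# round-trips to machine precision.
_YCBCR_FORWARD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168735891647856, -0.331264108352144, 0.5],
        [0.5, -0.418687589158345, -0.081312410841655],
    ]
)
_YCBCR_OFFSET = np.array([0.0, 0.5, 0.5])
_YCBCR_INVERSE = np.linalg.inv(_YCBCR_FORWARD)


def _as_plane(arr, name: str) -> np.ndarray:
    plane = np.asarray(arr, dtype=float)
    if plane.ndim != 2:
        raise ValueError(f"{name} plane must be 2-D, got shape {plane.shape}")
    return plane


@dataclass(frozen=True)
class RGBImage:
    """Three float planes in [0, 1] with identical shape."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        r = _as_plane(self.r, "r")
        g = _as_plane(self.g, "g")
        b = _as_plane(self.b, "b")
        if not (r.shape == g.shape == b.shape):
            raise ValueError("RGB planes must share one shape")
        object.__setattr__(self, "r", np.clip(r, 0.0, 1.0))
        object.__setattr__(self, "g", np.clip(g, 0.0, 1.0))
        object.__setattr__(self, "b", np.clip(b, 0.0, 1.0))

    @property
    def shape(self):
        return self.r.shape

    @classmethod
    def from_array(cls, arr) -> "RGBImage":
        """Build from an (H, W, 3) array."""
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3), got {arr.shape}")
        return cls(arr[..., 0], arr[..., 1], arr[..., 2])

    def to_array(self) -> np.ndarray:
        return np.stack([self.r, self.g, self.b], axis=-1)

    def luminance(self) -> np.ndarray:
        """Y plane (BT.601 luma row)."""
        w = YUV_FORWARD[0]
        return w[0] * self.r + w[1] * self.g + w[2] * self.b


@dataclass(frozen=True)
class YUVImage:
    """Luminance in [0, 1]; signed chrominance planes."""

    y: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        y = _as_plane(self.y, "y")
        u = _as_plane(self.u, "u")
        v = _as_plane(self.v, "v")
        if not (y.shape == u.shape == v.shape):
            raise ValueError("YUV planes must share one shape")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def shape(self):
        return self.y.shape


def _apply(matrix: np.ndarray, p0, p1, p2):
    out = [matrix[i, 0] * p0 + matrix[i, 1] * p1 + matrix[i, 2] * p2 for i in range(3)]
    return out[0], out[1], out[2]


def rgb_to_yuv(img: RGBImage, *, use_printed_matrix: bool = False) -> YUVImage:
    """Forward YUV conversion.

    With the standard matrix, gray pixels (r = g = b) map to u = v = 0
    exactly; `use_printed_matrix` selects the -0.1515 row-3 variant, which
    does not have this property.
    """
    m = YUV_FORWARD_PRINTED if use_printed_matrix else YUV_FORWARD
    y, u, v = _apply(m, img.r, img.g, img.b)
    return YUVImage(y, u, v)


def yuv_to_rgb(img: YUVImage) -> RGBImage:
    """Inverse YUV conversion; out-of-gamut values are clipped to [0, 1]."""
    r, g, b = _apply(YUV_INVERSE, img.y, img.u, img.v)
    return RGBImage(r, g, b)


def rgb_to_ycbcr(img: RGBImage) -> YUVImage:
    """Full-range BT.601 YCbCr; chroma planes are offset to center 0.5."""
    y, cb, cr = _apply(_YCBCR_FORWARD, img.r, img.g, img.b)
    return YUVImage(y, cb + _YCBCR_OFFSET[1], cr + _YCBCR_OFFSET[2])


def ycbcr_to_rgb(img: YUVImage) -> RGBImage:
    """Exact inverse of :func:`rgb_to_ycbcr` (up to clipping)."""
    r, g, b = _apply(_YCBCR_INVERSE, img.y, img.u - _YCBCR_OFFSET[1], img.v - _YCBCR_OFFSET[2])
    return RGBImage(r, g, b)
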