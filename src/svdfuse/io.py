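"""Raster I/O, configuration loading, and run provenance."""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .colorspace import RGBImage, YUV_FORWARD
from .denoise import BilateralParams, GuidedParams, NLMParams
from .fusion import FusionConfig
from .noise import NoiseSpec

__all__ = ["read_image", "write_image", "load_config", "RunRecord"]


def _normalize_codes(arr: np.ndarray) -> np.ndarray:
    """Integer raster codes -> floats in [0, 1] by the dtype's max code."""
    if np.issubdtype(arr.dtype, np.integer):
        max_code = float(np.iinfo(arr.dtype).max)
        return arr.astype(float) / max_code
    return np.clip(arr.astype(float), 0.0, 1.0)


def read_image(path, as_: str = "gray"):
    """Read a PNG/TIFF/JPEG file as a float image in [0, 1].

    ``as_='gray'`` collapses color files with the BT.601 luma weights;
    ``as_='rgb'`` returns an :class:`RGBImage` (grayscale files are
    replicated across channels).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = _normalize_codes(np.asarray(arr))
    if arr.ndim == 3 and arr.shape[2] >= 3:
        rgb = RGBImage(arr[..., 0], arr[..., 1], arr[..., 2])
    elif arr.ndim == 2:
        rgb = RGBImage(arr, arr, arr)
    else:
        raise OSError(f"unsupported image layout {arr.shape} in {path}")
    if as_ == "rgb":
        return rgb
    if as_ == "gray":
        w = YUV_FORWARD[0]
        return w[0] * rgb.r + w[1] * rgb.g + w[2] * rgb.b
    raise ValueError(f"as_ must be 'gray' or 'rgb', got {as_!r}")


def write_image(img, path, bit_depth: int = 8) -> None:
    """Write a float image (2-D plane or RGBImage) as PNG/TIFF.

    Values are clipped to [0, 1] and quantized to the requested depth
    (8-bit default; 16-bit for lossless pipelines, TIFF/PNG only).
    """
    path = Path(path)
    if isinstance(img, RGBImage):
        arr = img.to_array()
    else:
        arr = np.asarray(img, dtype=float)
    arr = np.clip(arr, 0.0, 1.0)
    if bit_depth == 8:
        coded = np.round(arr * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        coded = np.round(arr * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    try:
        iio.imwrite(path, coded)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot write image {path}: {exc}") from exc


_NOISE_KEYS = {f.name for f in dataclasses.fields(NoiseSpec)}
_PARAM_TYPES = {"bilateral": BilateralParams, "nlm": NLMParams, "guided": GuidedParams}


def load_config(path=None, overrides: dict | None = None) -> FusionConfig:
    """Load a FusionConfig from a YAML/JSON file (missing keys take
    defaults; unknown keys are rejected by name)."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(FusionConfig)}
    for key in data:
        if key not in known:
            raise ValueError(f"unknown config key: {key!r}")
    kwargs = {}
    for key, value in data.items():
        if key in ("mri_noise", "pet_noise"):
            if isinstance(value, dict):
                bad = set(value) - _NOISE_KEYS
                if bad:
                    raise ValueError(f"unknown keys in {key!r}: {sorted(bad)}")
                value = NoiseSpec(**value)
        elif key in _PARAM_TYPES and isinstance(value, dict):
            value = _PARAM_TYPES[key](**value)
        elif key == "k" and isinstance(value, str):
            if value.lower() == "full":
                value = None
            else:
                raise ValueError(f"invalid value for key 'k': {value!r}")
        kwargs[key] = value
    try:
        return FusionConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


@dataclasses.dataclass
class RunRecord:
    """Provenance sidecar written next to every CLI output."""

    command: str
    config: dict
    seed: int
    outputs: list
    stage_seconds: dict = dataclasses.field(default_factory=dict)
    versions: dict = dataclasses.field(default_factory=dict)
    started: float = dataclasses.field(default_factory=time.time)

    def stamp_versions(self):
        import numpy
        import scipy
        import skimage

        from . import __version__

        self.versions = {
            "svdfuse": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "python": platform.python_version(),
        }
        return self

    def save(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return f"<array shape={obj.shape}>"
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
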