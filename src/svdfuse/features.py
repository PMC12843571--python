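"""Convolutional feature extraction for high-frequency gating.

A VGG19-style backbone (3x3 kernels, stride 1, same-padding, channel widths
64 -> 512, 2x2 max-pooling between blocks, truncated before any fully
connected layers) produces feature maps whose global mean activation mu is
the scalar gate used in high-frequency fusion.  The network is implemented
directly on numpy (im2col + BLAS matmuls) with explicit backward passes, so
the optional self-consistency fine-tuning loop (Adam, StepLR, gradient
clipping, L1 feature-consistency loss) runs with no deep-learning framework.

ImageNet-pretrained weights are not bundled; the default weight source is a
seeded He-normal initialization, which the fusion algebra is insensitive to
(only scalar means of rectified activations are consumed).  Custom weights
can be loaded/saved via ``ConvBackbone.save`` / ``ConvBackbone.load``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize, rotate

__all__ = [
    "ConvBackbone",
    "TrainConfig",
    "FeatureGate",
    "make_backbone",
    "normalize_for_backbone",
    "mean_activation",
    "gate_from_hf",
    "consistency_loss",
    "finetune",
    "VGG19_ARCH",
    "SMALL_ARCH",
]

#: (width, n_convs) per block — the VGG19 convolutional backbone layout
VGG19_ARCH = ((64, 2), (128, 2), (256, 4), (512, 4), (512, 4))
#: scaled-down backbone of the same family, for fast CPU runs
SMALL_ARCH = ((4, 1), (8, 1), (16, 1), (32, 1), (32, 1))

INPUT_SIZE = 224


# ---------------------------------------------------------------------------
# layers


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, ksize: int):
    """x: (C, H, W); w: (O, C*k*k); b: (O,) -> y: (O, H, W) plus im2col cache."""
    c, h, wd = x.shape
    if ksize == 1:
        col = x.reshape(c, h * wd).T
    else:
        pad = ksize // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (ksize, ksize), axis=(1, 2))  # (C,H,W,k,k)
        col = win.transpose(1, 2, 0, 3, 4).reshape(h * wd, c * ksize * ksize)
    y = col @ w.T + b
    return np.ascontiguousarray(y.T.reshape(-1, h, wd)), col


def _conv_backward(dy: np.ndarray, col: np.ndarray, w: np.ndarray, x_shape, ksize: int):
    """Gradients of a same-padded convolution. Returns (dx, dw, db)."""
    c, h, wd = x_shape
    dy_flat = dy.reshape(dy.shape[0], h * wd).T  # (H*W, O)
    dw = dy_flat.T @ col
    db = dy_flat.sum(axis=0)
    dcol = dy_flat @ w  # (H*W, C*k*k)
    if ksize == 1:
        dx = dcol.T.reshape(c, h, wd)
        return dx, dw, db
    pad = ksize // 2
    dxp = np.zeros((c, h + 2 * pad, wd + 2 * pad), dtype=dy.dtype)
    dcol = dcol.reshape(h, wd, c, ksize, ksize).transpose(2, 3, 4, 0, 1)
    for ki in range(ksize):
        for kj in range(ksize):
            dxp[:, ki : ki + h, kj : kj + wd] += dcol[:, ki, kj]
    return dxp[:, pad : pad + h, pad : pad + wd], dw, db


def _pool_forward(x: np.ndarray):
    """2x2 max pool, stride 2 (spatial dims must be even)."""
    c, h, w = x.shape
    v = x.reshape(c, h // 2, 2, w // 2, 2)
    y = v.max(axis=(2, 4))
    # first-max mask for the backward pass
    flat = v.transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    return y, idx


def _pool_backward(dy: np.ndarray, idx: np.ndarray, x_shape):
    c, h, w = x_shape
    dflat = np.zeros((c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    return dflat.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


# ---------------------------------------------------------------------------
# backbone


class ConvBackbone:
    """Stack of conv+ReLU blocks separated by 2x2 max-pooling.

    ``arch`` is a tuple of (channel_width, n_convs) per block.  ``ksize=1``
    with ``identity_init=True`` yields the stub backbone used to make the
    fusion algebra testable by hand.
    """

    def __init__(self, arch=VGG19_ARCH, in_channels: int = 3, ksize: int = 3,
                 seed: int = 0, identity_init: bool = False, zero_init: bool = False):
        self.arch = tuple((int(w), int(n)) for w, n in arch)
        self.in_channels = in_channels
        self.ksize = ksize
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        rng = np.random.default_rng(seed)
        cin = in_channels
        for width, n_convs in self.arch:
            for _ in range(n_convs):
                fan_in = cin * ksize * ksize
                if zero_init:
                    w = np.zeros((width, fan_in), dtype=np.float32)
                elif identity_init:
                    if width != cin or ksize != 1:
                        raise ValueError("identity init needs ksize=1 and constant width")
                    w = np.eye(width, dtype=np.float32)
                else:
                    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(width, fan_in)).astype(np.float32)
                self.weights.append(w)
                self.biases.append(np.zeros(width, dtype=np.float32))
                cin = width

    @property
    def n_blocks(self) -> int:
        return len(self.arch)

    @property
    def deepest_channels(self) -> int:
        return self.arch[-1][0]

    def parameters(self):
        return self.weights + self.biases

    def forward(self, x: np.ndarray, upto_block: int | None = None, collect: bool = False):
        """Inference pass.

        Returns the activation after the last ReLU of ``upto_block``
        (1-based; default deepest).  ``collect=True`` returns the list of
        all per-block outputs instead.
        """
        x = np.asarray(x, dtype=np.float32)
        upto = self.n_blocks if upto_block is None else upto_block
        outs = []
        li = 0
        for bi, (width, n_convs) in enumerate(self.arch, start=1):
            for _ in range(n_convs):
                x, _ = _conv_forward(x, self.weights[li], self.biases[li], self.ksize)
                np.maximum(x, 0.0, out=x)
                li += 1
            outs.append(x)
            if bi == upto:
                break
            if min(x.shape[1:]) >= 2:
                x, _ = _pool_forward(x)
        return outs if collect else outs[upto - 1]

    def forward_with_cache(self, x: np.ndarray):
        """Training-mode pass; returns (deepest block activation, cache)."""
        x = np.asarray(x, dtype=np.float32)
        cache = []
        li = 0
        for bi, (width, n_convs) in enumerate(self.arch, start=1):
            for _ in range(n_convs):
                x_in_shape = x.shape
                y, col = _conv_forward(x, self.weights[li], self.biases[li], self.ksize)
                mask = y > 0
                x = y * mask
                cache.append(("conv", col, x_in_shape, mask, li))
                li += 1
            if bi < self.n_blocks and min(x.shape[1:]) >= 2:
                x_in_shape = x.shape
                x, idx = _pool_forward(x)
                cache.append(("pool", idx, x_in_shape))
        return x, cache

    def backward(self, grad: np.ndarray, cache) -> list[np.ndarray]:
        """Backprop; returns gradients aligned with :meth:`parameters`."""
        dws = [np.zeros_like(w) for w in self.weights]
        dbs = [np.zeros_like(b) for b in self.biases]
        dy = np.asarray(grad, dtype=np.float32)
        for entry in reversed(cache):
            if entry[0] == "pool":
                _, idx, x_shape = entry
                dy = _pool_backward(dy, idx, x_shape)
            else:
                _, col, x_shape, mask, li = entry
                dy = dy * mask
                dy, dw, db = _conv_backward(dy, col, self.weights[li], x_shape, self.ksize)
                dws[li] += dw
                dbs[li] += db
        return dws + dbs

    def save(self, path):
        np.savez(path, n=len(self.weights), ksize=self.ksize, in_channels=self.in_channels,
                 arch=np.asarray(self.arch),
                 **{f"w{i}": w for i, w in enumerate(self.weights)},
                 **{f"b{i}": b for i, b in enumerate(self.biases)})

    @classmethod
    def load(cls, path) -> "ConvBackbone":
        data = np.load(path)
        arch = tuple(map(tuple, data["arch"]))
        net = cls(arch=arch, in_channels=int(data["in_channels"]), ksize=int(data["ksize"]), zero_init=True)
        net.weights = [data[f"w{i}"] for i in range(int(data["n"]))]
        net.biases = [data[f"b{i}"] for i in range(int(data["n"]))]
        return net


def make_backbone(kind: str = "vgg19", seed: int = 0) -> ConvBackbone:
    """Factory for the named backbones.

    - ``vgg19``: full Table-2-style backbone (deepest block 512 channels),
      seeded He-normal weights.
    - ``small``: same block structure at reduced widths, for fast CPU runs.
    - ``stub``: one 1x1 identity convolution + ReLU; mu becomes the mean
      positive normalized intensity, hand-checkable.
    - ``zero``: all-zero weights (mu = 0 exactly), for degenerate-gate tests.
    """
    if kind == "vgg19":
        return ConvBackbone(VGG19_ARCH, seed=seed)
    if kind == "small":
        return ConvBackbone(SMALL_ARCH, seed=seed)
    if kind == "stub":
        return ConvBackbone(((3, 1),), ksize=1, identity_init=True)
    if kind == "zero":
        return ConvBackbone(((3, 1),), ksize=1, zero_init=True)
    raise ValueError(f"unknown backbone kind {kind!r}")


# ---------------------------------------------------------------------------
# feature interface


def normalize_for_backbone(img: np.ndarray, size: int = INPUT_SIZE) -> np.ndarray:
    """Map a [0, 1] plane to the network input: (I - 0.5) / 0.5 in [-1, 1],
    replicated to 3 channels, resized to ``size`` x ``size``."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, mode="reflect", anti_aliasing=False)
    norm = (img - 0.5) / 0.5
    return np.broadcast_to(norm, (3,) + norm.shape).astype(np.float32)


def mean_activation(extractor: ConvBackbone, img: np.ndarray, block: int | None = None) -> float:
    """Global mean of the (rectified) deepest-block feature map for ``img``."""
    feats = extractor.forward(normalize_for_backbone(img), upto_block=block)
    mu = float(feats.mean())
    if not np.isfinite(mu):
        raise FloatingPointError("non-finite feature activations")
    return mu


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


@dataclass(frozen=True)
class FeatureGate:
    """Scalar gate (mu_mri + mu_pet) / 2 from the two HF mean activations."""

    mu_mri: float
    mu_pet: float

    @property
    def gate(self) -> float:
        return 0.5 * (self.mu_mri + self.mu_pet)


def gate_from_hf(extractor: ConvBackbone, h_mri: np.ndarray, h_pet: np.ndarray,
                 block: int | None = None) -> FeatureGate:
    """Compute the HF fusion gate.

    The signed high-frequency residuals are min-max rescaled to [0, 1]
    before backbone normalization.
    """
    return FeatureGate(
        mu_mri=mean_activation(extractor, _minmax(h_mri), block),
        mu_pet=mean_activation(extractor, _minmax(h_pet), block),
    )


def consistency_loss(f1: np.ndarray, f2: np.ndarray, reduction: str = "mean") -> float:
    """L1 feature-consistency loss ||f1 - f2||_1 (mean reduction by default,
    making the value resolution-independent)."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("feature maps must share a shape")
    diff = np.abs(f1 - f2)
    if reduction == "mean":
        return float(diff.mean())
    if reduction == "sum":
        return float(diff.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


# ---------------------------------------------------------------------------
# fine-tuning (self-consistency across augmentations)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule for the consistency fine-tuning loop."""

    epochs: int = 10
    lr: float = 1e-5
    sched_step: int = 3
    sched_gamma: float = 0.7
    grad_clip_norm: float = 1.0
    seed: int = 0
    input_size: int = INPUT_SIZE
    rotation_deg: float = 15.0
    blur_sigma: tuple = (0.1, 2.0)
    brightness: float = 0.2
    contrast: float = 0.2

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be >= 0")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in force during 1-based ``epoch`` (StepLR)."""
        return self.lr * self.sched_gamma ** ((epoch - 1) // self.sched_step)


def augment(img: np.ndarray, rng: np.random.Generator, cfg: TrainConfig) -> np.ndarray:
    """Seeded augmentation: resize, horizontal flip (p=0.5), rotation within
    +/- rotation_deg, brightness/contrast jitter, Gaussian blur with sigma
    drawn from ``blur_sigma``.  Hue/saturation jitter degenerates to identity
    on the single-plane images used here."""
    from scipy.ndimage import gaussian_filter

    out = np.asarray(img, dtype=float)
    if out.shape != (cfg.input_size, cfg.input_size):
        out = resize(out, (cfg.input_size, cfg.input_size), order=1, mode="reflect", anti_aliasing=False)
    if rng.random() < 0.5:
        out = out[:, ::-1].copy()
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    out = rotate(out, angle, mode="symmetric", order=1)
    out = out * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    m = out.mean()
    out = m + (out - m) * rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)
    sigma = rng.uniform(*cfg.blur_sigma)
    out = gaussian_filter(out, sigma, mode="reflect")
    return np.clip(out, 0.0, 1.0)


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def _clip_global_norm(grads, max_norm: float) -> float:
    total = float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads)))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


def finetune(extractor: ConvBackbone, images: Sequence[np.ndarray], cfg: TrainConfig = TrainConfig()):
    """Self-consistency fine-tuning.

    Per epoch, each image is augmented and the L1 distance between the deep
    features of the original and augmented versions is minimized with Adam
    (gradient flows through both branches), a StepLR schedule, and global
    gradient-norm clipping.  Returns ``(extractor, history)`` where history
    records per-step losses, per-epoch learning rates and pre-clip gradient
    norms.
    """
    images = list(images)
    if not images:
        raise ValueError("image set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(extractor.parameters())
    history = {"loss": [], "lr": [], "grad_norm": [], "clipped_norm": []}
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.lr_at_epoch(epoch)
        history["lr"].append(lr)
        for img in images:
            aug = augment(img, rng, cfg)
            x1 = normalize_for_backbone(np.asarray(img, dtype=float), cfg.input_size)
            x2 = normalize_for_backbone(aug, cfg.input_size)
            f1, c1 = extractor.forward_with_cache(x1)
            f2, c2 = extractor.forward_with_cache(x2)
            diff = f1 - f2
            loss = float(np.abs(diff).mean())
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            g = (np.sign(diff) / diff.size).astype(np.float32)
            grads1 = extractor.backward(g, c1)
            grads2 = extractor.backward(-g, c2)
            grads = [a + b for a, b in zip(grads1, grads2)]
            norm = _clip_global_norm(grads, cfg.grad_clip_norm)
            history["loss"].append(loss)
            history["grad_norm"].append(norm)
            history["clipped_norm"].append(min(norm, cfg.grad_clip_norm))
            if lr > 0:
                opt.step(extractor.parameters(), grads, lr)
    return extractor, history
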