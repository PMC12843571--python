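"""SVD split of a luminance plane into low- and high-frequency parts.

I = U S V^T; the rank-k reconstruction L = U S_k V^T captures the smooth
structural content (the best rank-k approximation in the Frobenius norm), and
the residual H = I - L carries edges and fine texture.  Additivity L + H = I
holds by construction at every rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SVDDecomposition", "svd_decompose", "rank_sweep"]


@dataclass(frozen=True)
class SVDDecomposition:
    u_mat: np.ndarray
    s_vals: np.ndarray  # non-increasing, >= 0
    vt_mat: np.ndarray
    k: int | None  # None = full rank
    low: np.ndarray  # L = U S_k V^T
    high: np.ndarray  # H = I - L

    @property
    def discarded_energy(self) -> float:
        """Sum of squared singular values beyond rank k (Eckart-Young)."""
        k = len(self.s_vals) if self.k is None else self.k
        return float(np.sum(self.s_vals[k:] ** 2))


def svd_decompose(img: np.ndarray, k: int | None = None) -> SVDDecomposition:
    """Economy SVD with optional truncation rank.

    ``k=None`` keeps the full spectrum, in which case H is zero to rounding.
    Works on any H x W real matrix.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    u, s, vt = np.linalg.svd(img, full_matrices=False)
    rmax = len(s)
    if k is not None:
        if not 1 <= k <= rmax:
            raise ValueError(f"k must be in [1, {rmax}], got {k}")
        low = (u[:, :k] * s[:k]) @ vt[:k]
    else:
        low = (u * s) @ vt
    high = img - low
    # canonicalize so that low + high == img bit-exactly (two-sum identity)
    low = img - high
    return SVDDecomposition(u_mat=u, s_vals=s, vt_mat=vt, k=k, low=low, high=high)


def rank_sweep(mri: np.ndarray, pet, k_list, config=None, reference=None):
    """Run the full fusion pipeline at several truncation ranks.

    Returns a DataFrame with one row per rank: the truncation error
    ||L_k - I||_F of the MRI luminance plus fused-image quality metrics
    against ``reference`` (a ground-truth RGBImage) when given.  ``k_list``
    entries may be ints or None (full rank).
    """
    import pandas as pd  # local import keeps module load light

    from .fusion import FusionConfig, fuse_pair
    from .metrics import evaluate

    if config is None:
        config = FusionConfig()
    extractor = None
    if config.mode in ("svd_vgg", "vgg_only", "rgb_svd_vgg"):
        extractor = config.make_extractor()
    rows = []
    for k in k_list:
        cfg = config.with_rank(k)
        result = fuse_pair(mri, pet, cfg, extractor=extractor)
        dec = svd_decompose(np.asarray(result.provenance["mri_luminance"]), k)
        row = {
            "k": "full" if k is None else int(k),
            "trunc_err_fro": float(np.linalg.norm(dec.high)),
            "alpha": result.weights.alpha,
        }
        if reference is not None:
            row.update(evaluate(result, reference=reference).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
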