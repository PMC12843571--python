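"""Edge-preserving filters against brute-force evaluations of their
defining formulas (symmetric border padding throughout)."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from svdfuse import (
    BilateralParams,
    GuidedParams,
    NLMParams,
    NoiseSpec,
    bilateral,
    denoise_mri,
    denoise_pet,
    guided_filter,
    nlm,
)
from svdfuse.noise import apply_noise

# ---------------------------------------------------------------------------
# brute-force oracles (independent double-loop implementations)


def bilateral_bruteforce(img, p: BilateralParams):
    r = p.radius
    padded = np.pad(img, r, mode="symmetric")
    out = np.zeros_like(img)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            num = den = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    neighbor = padded[y + r + dy, x + r + dx]
                    ws = np.exp(-(dy**2 + dx**2) / (2 * p.sigma_s**2))
                    wr = np.exp(-((img[y, x] - neighbor) ** 2) / (2 * p.sigma_r**2))
                    num += ws * wr * neighbor
                    den += ws * wr
            out[y, x] = num / den
    return out


def spatial_gaussian_bruteforce(img, sigma_s, radius):
    padded = np.pad(img, radius, mode="symmetric")
    out = np.zeros_like(img)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            num = den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    w = np.exp(-(dy**2 + dx**2) / (2 * sigma_s**2))
                    num += w * padded[y + radius + dy, x + radius + dx]
                    den += w
            out[y, x] = num / den
    return out


def nlm_bruteforce(img, p: NLMParams):
    pr, sr = p.patch_radius, p.search_radius
    pad = pr + sr
    padded = np.pad(img, pad, mode="symmetric")
    out = np.zeros_like(img)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            cy, cx = y + pad, x + pad
            patch_c = padded[cy - pr : cy + pr + 1, cx - pr : cx + pr + 1]
            num = den = 0.0
            for dy in range(-sr, sr + 1):
                for dx in range(-sr, sr + 1):
                    ny, nx = cy + dy, cx + dx
                    patch_n = padded[ny - pr : ny + pr + 1, nx - pr : nx + pr + 1]
                    ssd = float(np.sum((patch_c - patch_n) ** 2))
                    w = np.exp(-ssd / p.h**2)
                    num += w * padded[ny, nx]
                    den += w
            out[y, x] = num / den
    return out


def guided_bruteforce(p_img, guide, gp: GuidedParams):
    # per-window coefficients a_k, b_k, then overlap-averaged over all
    # windows covering each pixel (windows clipped at the border match a
    # symmetric-padded box mean only in the interior, so pad explicitly)
    r = gp.radius
    pp = np.pad(p_img, r, mode="symmetric")
    gg = np.pad(guide, r, mode="symmetric")
    h, w = p_img.shape
    a = np.zeros((h + 2 * r, w + 2 * r))
    b = np.zeros_like(a)
    for y in range(r, r + h):
        for x in range(r, r + w):
            wi = gg[y - r : y + r + 1, x - r : x + r + 1]
            wp = pp[y - r : y + r + 1, x - r : x + r + 1]
            var = wi.var()
            cov = (wi * wp).mean() - wi.mean() * wp.mean()
            ak = cov / (var + gp.eps + gp.var_floor)
            a[y, x] = ak
            b[y, x] = wp.mean() - ak * wi.mean()
    # mirror the coefficient planes outward the same way before averaging
    a[:, :] = np.pad(a[r : r + h, r : r + w], r, mode="symmetric")
    b[:, :] = np.pad(b[r : r + h, r : r + w], r, mode="symmetric")
    out = np.zeros_like(p_img)
    for y in range(h):
        for x in range(w):
            mean_a = a[y : y + 2 * r + 1, x : x + 2 * r + 1].mean()
            mean_b = b[y : y + 2 * r + 1, x : x + 2 * r + 1].mean()
            out[y, x] = mean_a * guide[y, x] + mean_b
    return out


# ---------------------------------------------------------------------------
# bilateral


def test_bilateral_constant_invariance():
    img = np.full((10, 10), 0.42)
    p = BilateralParams(sigma_s=2.0, sigma_r=0.1, radius=3)
    assert np.allclose(bilateral(img, p), img, atol=1e-12)


def test_bilateral_matches_bruteforce(rng):
    img = rng.random((8, 8))
    p = BilateralParams(sigma_s=1.5, sigma_r=0.2, radius=2)
    assert np.abs(bilateral(img, p) - bilateral_bruteforce(img, p)).max() < 1e-10


def test_bilateral_huge_range_sigma_is_spatial_gaussian(rng):
    img = rng.random((10, 10))
    p = BilateralParams(sigma_s=2.0, sigma_r=1e6, radius=3)
    oracle = spatial_gaussian_bruteforce(img, 2.0, 3)
    assert np.abs(bilateral(img, p) - oracle).max() < 1e-6


# ---------------------------------------------------------------------------
# non-local means


def test_nlm_constant_invariance():
    img = np.full((12, 12), 0.7)
    assert np.allclose(nlm(img, NLMParams(h=0.1, patch_radius=2, search_radius=3)), img, atol=1e-12)


def test_nlm_matches_bruteforce_on_step(rng):
    img = np.zeros((12, 12))
    img[:, 6:] = 1.0
    img += 0.05 * rng.standard_normal(img.shape)
    p = NLMParams(h=0.3, patch_radius=2, search_radius=3)
    assert np.abs(nlm(img, p) - nlm_bruteforce(img, p)).max() < 1e-10


def test_nlm_huge_h_is_search_window_mean(rng):
    img = rng.random((10, 10))
    sr = 3
    p = NLMParams(h=1e6, patch_radius=1, search_radius=sr)
    padded = np.pad(img, sr, mode="symmetric")
    oracle = ndi.uniform_filter(padded, size=2 * sr + 1, mode="constant")[sr:-sr, sr:-sr]
    assert np.abs(nlm(img, p) - oracle).max() < 1e-6


def test_nlm_invalid_params_rejected():
    with pytest.raises(ValueError):
        NLMParams(h=0.1, patch_radius=4, search_radius=2)
    with pytest.raises(ValueError):
        NLMParams(h=0.0)


# ---------------------------------------------------------------------------
# guided filter


def test_guided_self_guidance_identity(rng):
    img = rng.random((12, 12))  # generic image: no constant windows
    gp = GuidedParams(radius=2, eps=0.0, var_floor=0.0)
    assert np.abs(guided_filter(img, img, gp) - img).max() < 1e-8


def test_guided_constant_guide_gives_box_mean(rng):
    p_img = rng.random((12, 12))
    guide = np.full((12, 12), 0.5)
    gp = GuidedParams(radius=2, eps=1e-4)
    out = guided_filter(p_img, guide, gp)
    box = ndi.uniform_filter(p_img, size=5, mode="reflect")
    box2 = ndi.uniform_filter(box, size=5, mode="reflect")  # b is averaged again
    assert np.abs(out - box2).max() < 1e-8


def test_guided_large_eps_approaches_box_mean(rng):
    p_img = rng.random((12, 12))
    guide = rng.random((12, 12))
    out = guided_filter(p_img, guide, GuidedParams(radius=2, eps=1e9))
    box2 = ndi.uniform_filter(ndi.uniform_filter(p_img, size=5, mode="reflect"), size=5, mode="reflect")
    assert np.abs(out - box2).max() < 1e-6


def test_guided_matches_bruteforce(rng):
    p_img = rng.random((10, 10))
    guide = rng.random((10, 10))
    gp = GuidedParams(radius=2, eps=1e-3)
    assert np.abs(guided_filter(p_img, guide, gp) - guided_bruteforce(p_img, guide, gp)).max() < 1e-10


def test_guided_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        guided_filter(np.zeros((4, 4)), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# modality wrappers


def test_denoise_pet_clean_constant_unchanged():
    from svdfuse import RGBImage

    img = RGBImage(np.full((20, 20), 0.8), np.full((20, 20), 0.3), np.full((20, 20), 0.1))
    out = denoise_pet(img, NLMParams(h=0.1, patch_radius=1, search_radius=2), GuidedParams(radius=2))
    for a, b in [(out.r, img.r), (out.g, img.g), (out.b, img.b)]:
        assert np.abs(a - b).max() < 1e-6
    assert out.shape == img.shape


def test_denoising_reduces_error_on_noisy_phantom(phantom64):
    noisy_mri = apply_noise(phantom64.mri, NoiseSpec(kind="gaussian", sigma2=0.01, seed=3))
    den = denoise_mri(noisy_mri, BilateralParams(sigma_s=2.0, sigma_r=0.15, radius=3))
    assert np.mean((den - phantom64.mri) ** 2) < np.mean((noisy_mri - phantom64.mri) ** 2)

    noisy_pet = apply_noise(phantom64.pet, NoiseSpec(kind="poisson", peak=50, seed=3))
    den_pet = denoise_pet(noisy_pet, NLMParams(h=0.3, patch_radius=1, search_radius=3), GuidedParams(radius=2))
    err_noisy = sum(np.mean((a - b) ** 2) for a, b in [
        (noisy_pet.r, phantom64.pet.r), (noisy_pet.g, phantom64.pet.g), (noisy_pet.b, phantom64.pet.b)])
    err_den = sum(np.mean((a - b) ** 2) for a, b in [
        (den_pet.r, phantom64.pet.r), (den_pet.g, phantom64.pet.g), (den_pet.b, phantom64.pet.b)])
    assert err_den < err_noisy
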