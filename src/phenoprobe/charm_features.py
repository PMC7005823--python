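"""Segmentation-free whole-image morphological feature bank.

Computes exactly 923 named features per grayscale probe-channel image, in
the style of the CHARM / WND-CHARM compound feature hierarchies: a stack of
image transforms (Fourier magnitude, wavelet detail, Chebyshev
reconstruction, edge magnitude, and compound paths) is built first, then
fixed-length feature families (pixel statistics, multiscale histograms,
direction-averaged Haralick textures, Tamura textures, Gabor energies,
Zernike moment magnitudes, Chebyshev coefficient histograms, Radon
projection statistics, Otsu-object statistics and comb moments) are
evaluated on selected transform planes.

The (transform plane x family) grid is the single source of truth for the
feature order; :func:`feature_manifest` exports it.  All planes are
contrast-stretched to [0, 1] before feature evaluation, so the bank is
invariant to absolute intensity scaling -- differences between images are
sensed through texture, granularity and intensity *distribution*, not
through raw brightness.

Degenerate statistics (e.g. the correlation of a constant co-occurrence
matrix) are imputed as 0 so every extraction yields 923 finite values.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
import pywt
from numpy.polynomial import chebyshev as npcheb
from scipy import ndimage, signal
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel, sobel, threshold_otsu
from skimage.measure import euler_number
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.transform import radon

logger = logging.getLogger(__name__)

N_FEATURES = 923

GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
CHEBYSHEV_ORDER = 20
ZERNIKE_DEGREE = 15  # 72 magnitudes
WAVELET = "sym5"
GABOR_BANK = (
    (0.05, 0.0),
    (0.05, np.pi / 2),
    (0.15, 0.0),
    (0.15, np.pi / 2),
    (0.25, 0.0),
    (0.25, np.pi / 2),
    (0.35, np.pi / 4),
)

PLANES = (
    "raw",
    "fourier",
    "wavelet",
    "chebyshev",
    "edge",
    "wavelet_of_fourier",
    "fourier_of_wavelet",
    "chebyshev_of_fourier",
)

_HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "diff_variance", "diff_entropy",
    "imc1", "imc2",
)

# families evaluated on every transform plane
_CORE_FAMILIES = ("pixel_stats", "multiscale_histograms", "haralick", "tamura")

# extra (plane, family) assignments completing the 923-feature grid
_EXTRA_ASSIGNMENT = (
    ("raw", "moments_comb"),
    ("fourier", "moments_comb"),
    ("wavelet", "moments_comb"),
    ("raw", "chebyshev_stats"),
    ("fourier", "chebyshev_stats"),
    ("raw", "chebyshev_fourier"),
    ("fourier", "chebyshev_fourier"),
    ("raw", "zernike"),
    ("raw", "gabor"),
    ("raw", "radon_stats"),
    ("fourier", "radon_stats"),
    ("raw", "otsu_object_stats"),
    ("edge", "edge_stats"),
)

FAMILIES = (
    "pixel_stats", "multiscale_histograms", "haralick", "gabor", "tamura",
    "zernike", "chebyshev_stats", "chebyshev_fourier", "radon_stats",
    "edge_stats", "otsu_object_stats", "moments_comb",
)


def plane_family_grid() -> list[tuple[str, str]]:
    """The ordered (transform plane, family) assignment defining the bank."""
    grid = [(pl, fam) for pl in PLANES for fam in _CORE_FAMILIES]
    grid.extend(_EXTRA_ASSIGNMENT)
    return grid


# ---------------------------------------------------------------------------
# small numeric helpers


def _rescale(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _finite(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    bad = ~np.isfinite(v)
    if bad.any():
        logger.warning("imputing %d non-finite feature value(s) as 0", bad.sum())
        v = np.where(bad, 0.0, v)
    return v


def _moments4(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, std, skewness, excess kurtosis with zero-variance guards."""
    x = np.asarray(x, dtype=float).ravel()
    m = float(x.mean())
    s = float(x.std())
    if s == 0:
        return m, 0.0, 0.0, 0.0
    z = (x - m) / s
    return m, s, float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# transform stack


def _fourier_plane(p: np.ndarray) -> np.ndarray:
    mag = np.abs(np.fft.fftshift(np.fft.fft2(p - p.mean())))
    return _rescale(np.log1p(mag))


def _wavelet_plane(p: np.ndarray) -> np.ndarray:
    cA, (cH, cV, cD) = pywt.dwt2(p, WAVELET)
    detail = np.sqrt(cH**2 + cV**2 + cD**2)
    return np.hstack([_rescale(cA), _rescale(detail)])


@lru_cache(maxsize=8)
def _cheb_pinv(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    v = npcheb.chebvander(x, order)
    return np.linalg.pinv(v)


def _cheb2d_coeffs(p: np.ndarray, order: int = CHEBYSHEV_ORDER) -> np.ndarray:
    py = _cheb_pinv(p.shape[0], order)
    px = _cheb_pinv(p.shape[1], order)
    return py @ p @ px.T


def _cheb_plane(p: np.ndarray) -> np.ndarray:
    c = _cheb2d_coeffs(p)
    x = np.linspace(-1.0, 1.0, p.shape[1])
    y = np.linspace(-1.0, 1.0, p.shape[0])
    vy = npcheb.chebvander(y, CHEBYSHEV_ORDER)
    vx = npcheb.chebvander(x, CHEBYSHEV_ORDER)
    return _rescale(vy @ c @ vx.T)


def transform_stack(image: np.ndarray) -> dict[str, np.ndarray]:
    """Build the named transform planes used by the feature grid.

    Returns the base planes (raw, Fourier magnitude, wavelet
    approximation+detail, Chebyshev reconstruction, edge magnitude) plus
    the compound paths; every plane is 2D and rescaled to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {image.shape}")
    if image.shape[0] < 64 or image.shape[1] < 64:
        raise ValueError("image must be at least 64x64 pixels")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    raw = _rescale(image)
    fourier = _fourier_plane(raw)
    wavelet = _wavelet_plane(raw)
    chebyshev = _cheb_plane(raw)
    edge = _rescale(sobel(raw))
    return {
        "raw": raw,
        "fourier": fourier,
        "wavelet": wavelet,
        "chebyshev": chebyshev,
        "edge": edge,
        "wavelet_of_fourier": _wavelet_plane(fourier),
        "fourier_of_wavelet": _fourier_plane(wavelet),
        "chebyshev_of_fourier": _cheb_plane(fourier),
    }


# ---------------------------------------------------------------------------
# feature families


def _pixel_stats(p: np.ndarray) -> np.ndarray:
    m, s, sk, ku = _moments4(p)
    return np.array([m, float(np.median(p)), s, float(p.min()), float(p.max()),
                     sk, ku])


def _pixel_stats_names() -> list[str]:
    return ["mean", "median", "std", "min", "max", "skewness", "kurtosis"]


_HIST_SCALES = (2, 4, 6, 8)


def _multiscale_histograms(p: np.ndarray) -> np.ndarray:
    out = []
    flat = p.ravel()
    for bins in _HIST_SCALES:
        counts, _ = np.histogram(flat, bins=bins, range=(0.0, 1.0))
        frac = counts / max(flat.size, 1)
        out.extend(frac)
        out.append(_entropy(frac))
    return np.array(out)


def _multiscale_histograms_names() -> list[str]:
    names = []
    for bins in _HIST_SCALES:
        names.extend(f"h{bins}_bin{i}" for i in range(bins))
        names.append(f"h{bins}_entropy")
    return names


def _quantize(p: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    return np.minimum((p * levels).astype(np.uint8), levels - 1)


def _haralick_13(P: np.ndarray) -> np.ndarray:
    """The 13 classic Haralick features of one normalized, symmetric GLCM."""
    n = P.shape[0]
    i = np.arange(n)[:, None].astype(float)
    j = np.arange(n)[None, :].astype(float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(n) * px).sum())
    mu_y = float((np.arange(n) * py).sum())
    sd_x = float(np.sqrt(((np.arange(n) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(n) - mu_y) ** 2 * py).sum()))

    asm = float((P**2).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((i - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    k_sum = np.arange(2 * n - 1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (np.arange(n)[:, None] + np.arange(n)[None, :]).ravel(),
              P.ravel())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy(p_sum) * np.log(2)  # natural-log convention

    entropy = _entropy(P.ravel()) * np.log(2)

    k_diff = np.arange(n)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).ravel(),
              P.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = _entropy(p_diff) * np.log(2)

    hx = _entropy(px) * np.log(2)
    hy = _entropy(py) * np.log(2)
    pxy = px[:, None] * py[None, :]
    nz = (P > 0)
    hxy1 = float(-(P[nz] * np.log(np.maximum(pxy[nz], 1e-300))).sum())
    nzp = pxy > 0
    hxy2 = float(-(pxy[nzp] * np.log(pxy[nzp])).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([asm, contrast, correlation, variance, idm, sum_avg,
                     sum_var, sum_ent, entropy, diff_var, diff_ent, imc1, imc2])


def haralick_avg_range(q: np.ndarray, distance: int = 1,
                       levels: int = GLCM_LEVELS) -> np.ndarray:
    """Direction-averaged + direction-range Haralick features (26 values)."""
    glcm = graycomatrix(q, distances=[distance], angles=list(GLCM_ANGLES),
                        levels=levels, symmetric=True, normed=False).astype(float)
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    if not np.all(sums > 0):
        return np.zeros(26)  # object smaller than the co-occurrence offset
    glcm /= sums
    per_angle = np.stack([_haralick_13(glcm[:, :, 0, a])
                          for a in range(len(GLCM_ANGLES))])
    return np.concatenate([per_angle.mean(axis=0),
                           per_angle.max(axis=0) - per_angle.min(axis=0)])


def _haralick(p: np.ndarray) -> np.ndarray:
    return haralick_avg_range(_quantize(p))


def _haralick_names() -> list[str]:
    return [f"{n}_avg" for n in _HARALICK_NAMES] + [
        f"{n}_range" for n in _HARALICK_NAMES]


def _tamura(p: np.ndarray) -> np.ndarray:
    # coarseness: best window size among 2^1..2^5 per pixel
    ks = (1, 2, 3, 4, 5)
    energies = []
    for k in ks:
        a = ndimage.uniform_filter(p, size=2**k, mode="reflect")
        h = np.abs(np.roll(a, -(2 ** (k - 1)), axis=1) -
                   np.roll(a, 2 ** (k - 1), axis=1))
        v = np.abs(np.roll(a, -(2 ** (k - 1)), axis=0) -
                   np.roll(a, 2 ** (k - 1), axis=0))
        energies.append(np.maximum(h, v))
    stack = np.stack(energies)
    best = np.argmax(stack, axis=0)  # ties -> smaller scale
    coarseness = float(np.mean(2.0 ** (best + 1))) / 2.0**5
    edges = [-0.5, 1.5, 2.5, 4.5]
    hist, _ = np.histogram(best, bins=edges)
    coarse_hist = hist / best.size

    m, s, _, ku = _moments4(p)
    contrast = float(s / (ku + 3.0) ** 0.25) if s > 0 and ku + 3.0 > 0 else 0.0

    gy = ndimage.sobel(p, axis=0, mode="reflect")
    gx = ndimage.sobel(p, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    thr = mag.mean()
    sel = mag > thr
    if sel.sum() > 0:
        theta = np.arctan2(gy[sel], gx[sel]) % np.pi
        hist_d, _ = np.histogram(theta, bins=16, range=(0, np.pi))
        frac = hist_d / hist_d.sum()
        directionality = float((frac**2).sum())
    else:
        directionality = 0.0
    return np.array([coarseness, *coarse_hist, contrast, directionality])


def _tamura_names() -> list[str]:
    return ["coarseness", "coarse_hist_fine", "coarse_hist_mid",
            "coarse_hist_large", "contrast", "directionality"]


@lru_cache(maxsize=8)
def _gabor_kernels() -> tuple[np.ndarray, ...]:
    return tuple(gabor_kernel(frequency=f, theta=t) for f, t in GABOR_BANK)


def _gabor(p: np.ndarray) -> np.ndarray:
    centred = p - p.mean()
    out = []
    for k in _gabor_kernels():
        resp = signal.fftconvolve(centred, k, mode="same")
        out.append(float(np.mean(np.abs(resp) ** 2)))
    return np.array(out)


def _gabor_names() -> list[str]:
    return [f"energy_f{f:g}_t{int(np.degrees(t))}" for f, t in GABOR_BANK]


def _zernike_indices(degree: int = ZERNIKE_DEGREE) -> list[tuple[int, int]]:
    return [(n, m) for n in range(degree + 1)
            for m in range(n % 2, n + 1, 2)]


@lru_cache(maxsize=4)
def _zernike_basis(shape: tuple[int, int],
                   degree: int = ZERNIKE_DEGREE):
    """Complex Zernike basis sampled on the inscribed disk; cached by shape."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(yy - cy, xx - cx) / radius
    inside = rho <= 1.0
    r = rho[inside]
    theta = np.arctan2(yy[inside] - cy, xx[inside] - cx)
    basis = []
    from math import factorial

    for n, m in _zernike_indices(degree):
        R = np.zeros_like(r)
        for s in range((n - m) // 2 + 1):
            c = ((-1) ** s * factorial(n - s) /
                 (factorial(s) * factorial((n + m) // 2 - s)
                  * factorial((n - m) // 2 - s)))
            R += c * r ** (n - 2 * s)
        basis.append(((n + 1) / np.pi) * R * np.exp(-1j * m * theta))
    return inside, np.array(basis, dtype=np.complex128)


def zernike_magnitudes(mask: np.ndarray,
                       degree: int = ZERNIKE_DEGREE) -> np.ndarray:
    """Rotation-invariant Zernike moment magnitudes of a binary mask."""
    inside, basis = _zernike_basis(mask.shape, degree)
    f = mask[inside].astype(float)
    area = max(inside.sum(), 1)
    return np.abs(basis @ f) / area


def _otsu_mask(p: np.ndarray) -> np.ndarray:
    if float(p.max() - p.min()) <= 0:
        return np.zeros_like(p, dtype=bool)
    return p > threshold_otsu(p)


def _zernike(p: np.ndarray) -> np.ndarray:
    return zernike_magnitudes(_otsu_mask(p))


def _zernike_names() -> list[str]:
    return [f"z{n}_{m}" for n, m in _zernike_indices()]


def _coef_histogram(c: np.ndarray, bins: int = 32) -> np.ndarray:
    c = c.ravel()
    peak = float(np.max(np.abs(c)))
    if peak <= 0:
        out = np.zeros(bins)
        out[bins // 2] = 1.0
        return out
    counts, _ = np.histogram(c / peak, bins=bins, range=(-1.0, 1.0))
    return counts / c.size


def _chebyshev_stats(p: np.ndarray) -> np.ndarray:
    return _coef_histogram(_cheb2d_coeffs(p))


def _chebyshev_fourier(p: np.ndarray) -> np.ndarray:
    return _coef_histogram(_cheb2d_coeffs(_fourier_plane(p)))


def _coefhist_names(prefix: str) -> list[str]:
    return [f"{prefix}_bin{i:02d}" for i in range(32)]


_RADON_ANGLES = (0.0, 45.0, 90.0, 135.0)


def _radon_stats(p: np.ndarray) -> np.ndarray:
    sino = radon(p, theta=list(_RADON_ANGLES), circle=False,
                 preserve_range=True)
    out = []
    for a in range(sino.shape[1]):
        proj = sino[:, a]
        out.extend([float(proj.mean()), float(proj.std()), float(proj.max())])
    return np.array(out)


def _radon_names() -> list[str]:
    return [f"a{int(a)}_{s}" for a in _RADON_ANGLES
            for s in ("mean", "std", "max")]


def _edge_stats(p: np.ndarray) -> np.ndarray:
    mag = sobel(p)
    gy = ndimage.sobel(p, axis=0, mode="reflect")
    gx = ndimage.sobel(p, axis=1, mode="reflect")
    feats = [float(mag.mean()), float(mag.std()), float(np.median(mag)),
             float(mag.max())]
    if float(mag.max() - mag.min()) > 0:
        frac = float((mag > threshold_otsu(mag)).mean())
    else:
        frac = 0.0
    feats.append(frac)
    total = mag.sum()
    if total > 0:
        theta = np.arctan2(gy, gx) % np.pi
        hist, _ = np.histogram(theta, bins=4, range=(0, np.pi),
                               weights=mag)
        feats.extend(hist / total)
        c = (mag * np.cos(2 * theta)).sum() / total
        s = (mag * np.sin(2 * theta)).sum() / total
        feats.append(float(np.hypot(c, s)))
    else:
        feats.extend([0.0] * 5)
    return np.array(feats)


def _edge_stats_names() -> list[str]:
    return ["mag_mean", "mag_std", "mag_median", "mag_max", "edge_fraction",
            "dir_bin0", "dir_bin1", "dir_bin2", "dir_bin3", "dir_resultant"]


_OBJ_PROPS = ("area", "eccentricity", "solidity", "extent", "perimeter")


def _otsu_object_stats(p: np.ndarray) -> np.ndarray:
    mask = _otsu_mask(p)
    labels = sk_label(mask, connectivity=2)
    # drop speckles below 5 px so property statistics describe objects
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < 5)
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels = sk_label(labels > 0, connectivity=2)
    props = regionprops(labels)
    n = len(props)
    if n == 0:
        return np.zeros(34)
    feats = [float(n), float(mask.mean()),
             float(euler_number(mask, connectivity=2)),
             float(max(pr.area for pr in props) / mask.size)]
    for name in _OBJ_PROPS:
        vals = np.array([getattr(pr, name) for pr in props], dtype=float)
        feats.extend([float(vals.mean()), float(vals.std()),
                      float(vals.min()), float(vals.max())])
    for name in ("equivalent_diameter_area", "axis_major_length",
                 "axis_minor_length", "orientation"):
        vals = np.array([getattr(pr, name) for pr in props], dtype=float)
        feats.extend([float(vals.mean()), float(vals.std())])
    centre = np.array(p.shape, dtype=float) / 2.0
    d = np.array([np.hypot(*(np.array(pr.centroid) - centre)) for pr in props])
    feats.extend([float(d.mean()), float(d.std())])
    return np.array(feats)


def _otsu_object_names() -> list[str]:
    names = ["n_objects", "fg_fraction", "euler_number", "largest_area_frac"]
    for p in _OBJ_PROPS:
        names.extend(f"{p}_{s}" for s in ("mean", "std", "min", "max"))
    for p in ("eqdiam", "major_axis", "minor_axis", "orientation"):
        names.extend(f"{p}_{s}" for s in ("mean", "std"))
    names.extend(["centroid_dist_mean", "centroid_dist_std"])
    return names


_COMB_DIRS = ("rows", "cols", "diag", "adiag")
_LINE_STATS = ("mean", "std", "skew", "kurt")
_AGGS = ("mean", "std", "range")


def _nan_line_stats(m: np.ndarray) -> np.ndarray:
    """(L, 4) mean/std/skew/kurt per row of a NaN-padded line matrix."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(m, axis=1)
        std = np.nanstd(m, axis=1)
        z = (m - mean[:, None]) / np.where(std > 0, std, 1.0)[:, None]
        skew = np.nanmean(z**3, axis=1)
        kurt = np.nanmean(z**4, axis=1) - 3.0
    zero = std == 0
    skew[zero] = 0.0
    kurt[zero] = 0.0
    return np.column_stack([mean, std, skew, kurt])


def _comb_line_matrix(p: np.ndarray, direction: str) -> np.ndarray:
    if direction == "rows":
        return p
    if direction == "cols":
        return p.T
    src = p if direction == "diag" else np.fliplr(p)
    h, w = src.shape
    offs = [k for k in range(-(h - 8), w - 7)]
    maxlen = min(h, w)
    m = np.full((len(offs), maxlen), np.nan)
    for i, k in enumerate(offs):
        d = np.diagonal(src, offset=k)
        m[i, :d.size] = d
    return m


def _moments_comb(p: np.ndarray) -> np.ndarray:
    out = []
    for direction in _COMB_DIRS:
        stats = _nan_line_stats(_comb_line_matrix(p, direction))
        for si in range(4):
            col = stats[:, si]
            out.extend([float(col.mean()), float(col.std()),
                        float(col.max() - col.min())])
    return np.array(out)


def _moments_comb_names() -> list[str]:
    return [f"{d}_{s}_{a}" for d in _COMB_DIRS for s in _LINE_STATS
            for a in _AGGS]


_FAMILY_FUNCS = {
    "pixel_stats": (_pixel_stats, _pixel_stats_names),
    "multiscale_histograms": (_multiscale_histograms,
                              _multiscale_histograms_names),
    "haralick": (_haralick, _haralick_names),
    "gabor": (_gabor, _gabor_names),
    "tamura": (_tamura, _tamura_names),
    "zernike": (_zernike, _zernike_names),
    "chebyshev_stats": (_chebyshev_stats,
                        lambda: _coefhist_names("cheb")),
    "chebyshev_fourier": (_chebyshev_fourier,
                          lambda: _coefhist_names("chebfft")),
    "radon_stats": (_radon_stats, _radon_names),
    "edge_stats": (_edge_stats, _edge_stats_names),
    "otsu_object_stats": (_otsu_object_stats, _otsu_object_names),
    "moments_comb": (_moments_comb, _moments_comb_names),
}


def extract_family(plane: np.ndarray, family: str) -> np.ndarray:
    """Evaluate one feature family on one transform plane."""
    if family not in _FAMILY_FUNCS:
        raise ValueError(
            f"unknown family {family!r}; valid families: {sorted(_FAMILY_FUNCS)}"
        )
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("plane must be 2D")
    func, names = _FAMILY_FUNCS[family]
    values = _finite(func(plane))
    expected = len(names())
    if values.size != expected:
        raise AssertionError(
            f"family {family} produced {values.size} values, expected {expected}"
        )
    return values


def family_length(family: str) -> int:
    return len(_FAMILY_FUNCS[family][1]())


@lru_cache(maxsize=1)
def feature_manifest() -> pd.DataFrame:
    """The ordered 923-row manifest: feature_name, family, transform_path."""
    rows = []
    for plane, family in plane_family_grid():
        for sub in _FAMILY_FUNCS[family][1]():
            rows.append({
                "feature_name": f"{plane}|{family}|{sub}",
                "family": family,
                "transform_path": plane,
            })
    df = pd.DataFrame(rows)
    assert len(df) == N_FEATURES, f"manifest has {len(df)} rows"
    assert df["feature_name"].is_unique
    return df


def feature_names() -> list[str]:
    return feature_manifest()["feature_name"].tolist()


def extract_charm(image: np.ndarray) -> np.ndarray:
    """Extract the full 923-feature vector from one grayscale image.

    A pure function of the pixel data: the same image always yields a
    bitwise-identical vector.
    """
    planes = transform_stack(image)
    chunks = [extract_family(planes[plane], family)
              for plane, family in plane_family_grid()]
    vec = np.concatenate(chunks)
    assert vec.size == N_FEATURES
    return vec


def write_manifest(path) -> None:
    feature_manifest().to_csv(path, index=False)
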