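"""Texture and tile-level feature families.

Haralick's 13 gray-level co-occurrence matrix (GLCM) statistics are
implemented from the original 1973 definitions: intensities are linearly
quantized to ``levels`` gray bins over the region's min-max range, a
symmetric normalized GLCM is accumulated for each of the four 1-px offsets
(0, 45, 90, 135 degrees), the 13 statistics are computed per direction and
averaged.  Constant regions (single-level GLCM) use the documented
degenerate convention: contrast/entropy-type features are 0 and correlation
is 0.

Also here: the granularity spectrum (volume removed by morphological
openings of increasing radius), stain colocalization statistics, and
whole-tile image-quality scores.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

HARALICK_NAMES = [
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "infomeas1", "infomeas2",
]

_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees


def quantize(values: np.ndarray, levels: int = 8) -> np.ndarray:
    """Linear min-max quantization to integer levels 0..levels-1."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = ((values - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def glcm(quantized: np.ndarray, offset: tuple[int, int], levels: int,
         region: np.ndarray | None = None) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one pixel offset.

    Only pairs whose both pixels lie inside ``region`` (default: everywhere)
    are counted.  Returns a ``levels x levels`` matrix summing to 1, or a
    zero matrix if the region contains no valid pair.
    """
    dr, dc = offset
    h, w = quantized.shape
    if region is None:
        region = np.ones((h, w), dtype=bool)
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = quantized[r0s:r0e, c0s:c0e]
    b = quantized[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    va = region[r0s:r0e, c0s:c0e]
    vb = region[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    ok = va & vb
    if not ok.any():
        return np.zeros((levels, levels))
    p = np.bincount((a[ok] * levels + b[ok]).ravel(),
                    minlength=levels * levels).reshape(levels, levels).astype(float)
    p = p + p.T  # symmetric
    return p / p.sum()


def haralick_from_glcm(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized symmetric GLCM."""
    levels = p.shape[0]
    if p.sum() == 0:
        return np.zeros(13)
    eps = np.finfo(float).tiny
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = (i * px).sum()
    sigma2 = ((i - mu) ** 2 * px).sum()
    sigma = np.sqrt(sigma2)

    asm = (p ** 2).sum()
    contrast = ((ii - jj) ** 2 * p).sum()
    if sigma > 0:
        correlation = ((ii - mu) * (jj - mu) * p).sum() / sigma2
    else:
        correlation = 0.0
    variance = ((ii - mu) ** 2 * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()

    # p_{x+y}(k), k = 0 .. 2*levels-2  and  p_{x-y}(k), k = 0 .. levels-1
    psum = np.bincount((ii + jj).ravel(), weights=p.ravel(),
                       minlength=2 * levels - 1)
    pdiff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(),
                        minlength=levels)
    k_sum = np.arange(2 * levels - 1)
    k_diff = np.arange(levels)

    sum_average = (k_sum * psum).sum()
    sum_entropy = -(psum * np.log(psum + eps)).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * psum).sum()
    entropy = -(p * np.log(p + eps)).sum()
    diff_average = (k_diff * pdiff).sum()
    difference_variance = ((k_diff - diff_average) ** 2 * pdiff).sum()
    difference_entropy = -(pdiff * np.log(pdiff + eps)).sum()

    py = p.sum(axis=0)
    hx = -(px * np.log(px + eps)).sum()
    hy = -(py * np.log(py + eps)).sum()
    pxpy = np.outer(px, py)
    hxy1 = -(p * np.log(pxpy + eps)).sum()
    hxy2 = -(pxpy * np.log(pxpy + eps)).sum()
    denom = max(hx, hy)
    infomeas1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    infomeas2 = np.sqrt(max(arg, 0.0))

    return np.array([asm, contrast, correlation, variance, idm, sum_average,
                     sum_variance, sum_entropy, entropy, difference_variance,
                     difference_entropy, infomeas1, infomeas2])


def haralick(image: np.ndarray, region: np.ndarray | None = None,
             levels: int = 8) -> np.ndarray:
    """13 Haralick features of ``image`` (restricted to ``region`` if given),
    averaged over the four 1-px directions.

    A region with fewer than 2 pixels, or constant intensity, returns the
    degenerate all-zero convention (except ASM/IDM which are 1 for a
    deterministic single-level GLCM).
    """
    image = np.asarray(image, dtype=float)
    if region is None:
        region = np.ones(image.shape, dtype=bool)
    vals = image[region]
    if vals.size < 2 or np.ptp(vals) == 0:
        out = np.zeros(13)
        if vals.size >= 2:
            out[0] = 1.0   # ASM of the single-level GLCM
            out[4] = 1.0   # IDM likewise
        return out
    q = np.zeros(image.shape, dtype=np.intp)
    q[region] = quantize(vals, levels)
    feats = [haralick_from_glcm(glcm(q, off, levels, region)) for off in _OFFSETS]
    return np.mean(feats, axis=0)


def haralick_per_object(mask, image, levels: int = 8, prefix: str = "haralick"):
    """Per-object Haralick table (one row per label)."""
    import pandas as pd

    rows = {int(k): haralick(image, region=mask.labels == k, levels=levels)
            for k in mask.label_ids()}
    cols = [f"{prefix}_{n}" for n in HARALICK_NAMES]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _diamond_footprint(radius: int) -> np.ndarray:
    """L1 ball of the given radius (i-fold Minkowski sum of the unit cross)."""
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (np.abs(yy) + np.abs(xx)) <= radius


def granularity_spectrum(image: np.ndarray, n_scales: int = 16) -> np.ndarray:
    """Morphological granularity spectrum of a grayscale (OD) image.

    Element ``i`` (1-based) is the percentage of image volume removed
    between grayscale openings with structuring elements of radius ``i-1``
    and ``i``, relative to the original volume.  The structuring elements
    are L1 balls (iterated Minkowski sums of the unit cross): unlike
    rasterized Euclidean disks, these form a true granulometry, so opening
    volume is guaranteed non-increasing in radius and the spectrum is
    non-negative with sum <= 100.
    """
    image = np.asarray(image, dtype=float)
    total = image.sum()
    if total <= 0:
        return np.zeros(n_scales)
    prev = image.sum()
    out = np.empty(n_scales)
    for i in range(1, n_scales + 1):
        fp = _diamond_footprint(i)
        # outside-image samples are ignored (not reflected or padded)
        eroded = ndimage.grey_erosion(image, footprint=fp, mode="constant",
                                      cval=np.inf)
        opened = ndimage.grey_dilation(eroded, footprint=fp, mode="constant",
                                       cval=-np.inf)
        vol = opened.sum()
        out[i - 1] = 100.0 * (prev - vol) / total
        prev = vol
    return out


def colocalization(h_channel: np.ndarray, e_channel: np.ndarray,
                   region: np.ndarray | None = None) -> dict[str, float]:
    """Stain colocalization: Pearson r, overlap coefficient, Manders M1/M2.

    Manders thresholds are Otsu on each channel (auto-threshold); a
    zero-variance channel gives r = 0 by convention.
    """
    from skimage.filters import threshold_otsu

    h = np.asarray(h_channel, dtype=float)
    e = np.asarray(e_channel, dtype=float)
    if region is not None:
        h, e = h[region], e[region]
    else:
        h, e = h.ravel(), e.ravel()
    if h.size == 0:
        return {"pearson_r": 0.0, "overlap": 0.0, "manders_m1": 0.0,
                "manders_m2": 0.0}
    sh, se = h.std(), e.std()
    if sh > 0 and se > 0:
        r = float(np.mean((h - h.mean()) * (e - e.mean())) / (sh * se))
    else:
        r = 0.0
    denom = np.sqrt((h ** 2).sum() * (e ** 2).sum())
    overlap = float((h * e).sum() / denom) if denom > 0 else 0.0
    th = threshold_otsu(h) if np.ptp(h) > 0 else np.inf
    te = threshold_otsu(e) if np.ptp(e) > 0 else np.inf
    hsum, esum = h.sum(), e.sum()
    m1 = float(h[e > te].sum() / hsum) if hsum > 0 and np.isfinite(te) else 0.0
    m2 = float(e[h > th].sum() / esum) if esum > 0 and np.isfinite(th) else 0.0
    return {"pearson_r": r, "overlap": overlap, "manders_m1": m1, "manders_m2": m2}


def focus_score(gray: np.ndarray) -> float:
    """Log-log slope of the radially averaged power spectrum.

    Blurring removes high-frequency power, making the slope more negative;
    sharper images score higher.
    """
    gray = np.asarray(gray, dtype=float)
    f = np.fft.fftshift(np.fft.fft2(gray - gray.mean()))
    power = np.abs(f) ** 2
    h, w = gray.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h / 2, xx - w / 2).astype(int)
    rmax = int(r.max())  # out to the spectrum corners (diagonal Nyquist)
    radii = np.arange(1, rmax + 1)
    radial = ndimage.sum_labels(power, r, radii)
    counts = ndimage.sum_labels(np.ones_like(power), r, radii)
    radial = radial / np.maximum(counts, 1)
    if radial.max() <= 0:
        return -20.0  # flat image: no spectral content at all (floor value)
    # a relative floor keeps empty bins finite without dominating the fit
    logp = np.log(radial + 1e-12 * radial.max())
    slope = np.polyfit(np.log(radii), logp, 1)[0]
    return float(slope)


def image_quality(pixels: np.ndarray) -> dict[str, float]:
    """Whole-tile quality scores: focus, percent saturated, percent minimal."""
    pixels = np.asarray(pixels, dtype=float)
    gray = pixels.mean(axis=-1) if pixels.ndim == 3 else pixels
    return {
        "focus_score": focus_score(gray),
        "percent_saturated": float((gray >= 254).mean() * 100.0),
        "percent_minimal": float((gray <= 1).mean() * 100.0),
    }
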