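"""Per-object feature families: intensity, radial distribution, shape,
Zernike moments, and nuclear neighborhood.

All functions take an integer :class:`~pathomics.segmentation.LabelMask`
(and, where relevant, a co-registered OD image) and return a
``pandas.DataFrame`` with one row per object, indexed by label, with stable
``family_measure`` column names.  Intensity-bearing features are computed on
stain OD channels, not raw RGB.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from ..segmentation import LabelMask

INTENSITY_COLUMNS = ["integrated", "mean", "median", "std", "mad", "min", "max",
                     "q25", "q75", "edge_mean"]


def intensity_features(mask: LabelMask, image: np.ndarray,
                       prefix: str = "intensity") -> pd.DataFrame:
    """Distributional intensity statistics per object.

    ``edge_mean`` averages the object's border pixels (pixels with at least
    one 4-neighbor outside the object).
    """
    image = np.asarray(image, dtype=float)
    labels = mask.labels
    rows = {}
    cross = ndimage.generate_binary_structure(2, 1)
    for k in mask.label_ids():
        sel = labels == k
        v = image[sel]
        border = sel & ~ndimage.binary_erosion(sel, structure=cross)
        edge = image[border]
        if edge.size == 0:
            edge = v
        rows[int(k)] = [
            float(v.sum()), float(v.mean()), float(np.median(v)), float(v.std()),
            float(np.median(np.abs(v - np.median(v)))), float(v.min()), float(v.max()),
            float(np.percentile(v, 25)), float(np.percentile(v, 75)),
            float(edge.mean()),
        ]
    cols = [f"{prefix}_{c}" for c in INTENSITY_COLUMNS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def radial_distribution(mask: LabelMask, image: np.ndarray, n_rings: int = 4,
                        n_wedges: int = 8, prefix: str = "radial") -> pd.DataFrame:
    """Radial intensity distribution per object.

    Pixels are binned into ``n_rings`` equal-width bands of normalized
    distance from the object centroid (distance divided by the object's
    maximum centroid distance).  Per ring:

    - ``fracatd``: fraction of total object intensity falling in the ring;
    - ``meanfrac``: ``fracatd`` divided by the ring's pixel fraction
      (1.0 everywhere for a uniform object);
    - ``radialcv``: coefficient of variation of mean intensity over
      ``n_wedges`` angular wedges within the ring (0 for angular uniformity).
    """
    image = np.asarray(image, dtype=float)
    labels = mask.labels
    rows = {}
    for k in mask.label_ids():
        rr, cc = np.nonzero(labels == k)
        v = image[rr, cc]
        cy, cx = rr.mean(), cc.mean()
        d = np.hypot(rr - cy, cc - cx)
        dmax = d.max()
        norm = d / dmax if dmax > 0 else np.zeros_like(d)
        ring = np.minimum((norm * n_rings).astype(int), n_rings - 1)
        theta = np.arctan2(rr - cy, cc - cx)
        wedge = np.minimum(((theta + np.pi) / (2 * np.pi) * n_wedges).astype(int),
                           n_wedges - 1)
        total = v.sum()
        n_px = v.size
        feats = []
        for b in range(n_rings):
            in_ring = ring == b
            ring_sum = v[in_ring].sum()
            frac_at_d = ring_sum / total if total > 0 else 0.0
            px_frac = in_ring.sum() / n_px
            mean_frac = frac_at_d / px_frac if px_frac > 0 else 0.0
            wedge_means = [v[in_ring & (wedge == w)].mean()
                           for w in range(n_wedges)
                           if np.any(in_ring & (wedge == w))]
            if len(wedge_means) >= 2 and np.mean(wedge_means) != 0:
                cv = float(np.std(wedge_means) / np.mean(wedge_means))
            else:
                cv = 0.0
            feats += [float(frac_at_d), float(mean_frac), cv]
        rows[int(k)] = feats
    cols = []
    for b in range(1, n_rings + 1):
        cols += [f"{prefix}_fracatd_{b}", f"{prefix}_meanfrac_{b}",
                 f"{prefix}_radialcv_{b}"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _min_feret(coords: np.ndarray, n_angles: int = 180) -> float:
    """Minimum Feret (caliper) diameter via projection over rotations."""
    if len(coords) == 1:
        return 1.0
    pts = coords.astype(float)
    angles = np.linspace(0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T  # points x angles
    widths = proj.max(axis=0) - proj.min(axis=0) + 1.0  # +1: pixel extent
    return float(widths.min())


def _hull_area(coords: np.ndarray) -> float:
    """Convex hull area over pixel centers.  For a convex rasterized object
    this matches the pixel count to within rasterization error, so solidity
    is ~1 rather than biased low by boundary bumps."""
    from scipy.spatial import ConvexHull, QhullError

    try:
        return float(ConvexHull(coords).volume)
    except QhullError:  # degenerate (collinear) object
        return float(len(coords))


def shape_features(mask: LabelMask, prefix: str = "shape") -> pd.DataFrame:
    """Standard geometric descriptors per object.

    ``form_factor`` is ``4*pi*A / P**2`` (1 for a perfect circle, smaller
    for irregular outlines); the perimeter is the 4-direction Crofton
    estimate, which is unbiased for smooth outlines where the naive contour
    length overestimates.
    """
    from skimage.measure import perimeter_crofton

    rows = {}
    for rp in regionprops(mask.labels):
        area = float(rp.area)
        perim = float(perimeter_crofton(rp.image, directions=4))
        if perim <= 0:
            perim = 1.0
        form = min(4.0 * np.pi * area / perim ** 2, 1.0)
        solidity = min(area / _hull_area(rp.coords.astype(float)), 1.0)
        rows[int(rp.label)] = [
            area, perim, float(rp.eccentricity), solidity,
            float(rp.extent), form, float(rp.axis_major_length),
            float(rp.axis_minor_length), float(rp.orientation),
            float(rp.feret_diameter_max), _min_feret(rp.coords),
        ]
    cols = [f"{prefix}_{c}" for c in
            ["area", "perimeter", "eccentricity", "solidity", "extent",
             "form_factor", "major_axis", "minor_axis", "orientation",
             "feret_max", "feret_min"]]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def zernike_indices(max_degree: int = 9) -> list[tuple[int, int]]:
    """(n, m) index pairs with n <= max_degree, m >= 0, n - m even."""
    return [(n, m) for n in range(max_degree + 1) for m in range(n + 1)
            if (n - m) % 2 == 0]


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^m(rho)."""
    from math import factorial

    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * factorial(n - s)
             / (factorial(s) * factorial((n + m) // 2 - s)
                * factorial((n - m) // 2 - s)))
        out = out + c * rho ** (n - 2 * s)
    return out


def zernike_magnitudes(binary: np.ndarray, max_degree: int = 9) -> np.ndarray:
    """Zernike moment magnitudes |Z_nm| of one binary object.

    The object is mapped onto its minimum enclosing disk (center = centroid,
    radius = maximum centroid-to-pixel distance); the coefficients are the
    least-squares projection of the object indicator onto the Zernike basis
    evaluated at the lattice points of that disk.  In the continuum limit
    this equals the standard moment ``(n+1)/pi * <f, V_nm>`` (the basis is
    orthogonal on the disk with norm ``pi/(n+1)``), while on the discrete
    lattice it keeps two exact properties the plain sum lacks: a full disk
    has |Z_nm| = 0 for every n >= 1 (orthogonality to the constant holds by
    construction), and 90-degree raster rotations leave all magnitudes
    unchanged (the sample set is rotated rigidly, so the Gram matrix is
    conjugated by a unitary phase).
    """
    rr, cc = np.nonzero(binary)
    idx = zernike_indices(max_degree)
    if rr.size == 0:
        return np.zeros(len(idx))
    cy, cx = rr.mean(), cc.mean()
    radius = float(np.hypot(rr - cy, cc - cx).max())
    if radius == 0:
        return np.array([1.0] + [0.0] * (len(idx) - 1))
    h, w = binary.shape
    r0, r1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius))
    c0, c1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius))
    yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    y = (yy - cy) / radius
    x = (xx - cx) / radius
    rho = np.hypot(x, y)
    inside = rho <= 1.0
    f = np.zeros(rho.shape)
    valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    f[valid] = binary[yy[valid], xx[valid]]
    rho_s = rho[inside]
    theta_s = np.arctan2(y, x)[inside]
    basis = np.stack([_radial_poly(n, m, rho_s) * np.exp(1j * m * theta_s)
                      for n, m in idx], axis=1)
    coef, *_ = np.linalg.lstsq(basis, f[inside].astype(complex), rcond=None)
    return np.abs(coef)


def zernike_shape(mask: LabelMask, max_degree: int = 9,
                  prefix: str = "zernike") -> pd.DataFrame:
    """Zernike magnitudes per object (30 values at degree 9)."""
    idx = zernike_indices(max_degree)
    rows = {}
    labels = mask.labels
    for rp in regionprops(labels):
        rows[int(rp.label)] = zernike_magnitudes(rp.image, max_degree)
    cols = [f"{prefix}_{n}_{m}" for n, m in idx]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def neighbor_features(mask: LabelMask, expand_distance: float = 5.0,
                      prefix: str = "neighbors") -> pd.DataFrame:
    """Neighbor count and percent-touching per object.

    A neighbor is any distinct label whose pixels come within
    ``expand_distance`` of the object's boundary; percent touching is the
    fraction of boundary pixels that lie within that distance of another
    object.
    """
    labels = mask.labels
    rows = {}
    ids = mask.label_ids()
    for k in ids:
        obj = labels == k
        # distance from every pixel to the nearest *other* object
        others = (labels > 0) & ~obj
        if not others.any():
            rows[int(k)] = [0.0, 0.0]
            continue
        d_other = ndimage.distance_transform_edt(~others)
        eroded = ndimage.binary_erosion(obj)
        boundary = obj & ~eroded
        br, bc = np.nonzero(boundary)
        if br.size == 0:
            br, bc = np.nonzero(obj)
        near = d_other[br, bc] <= expand_distance
        # labels reachable within the distance from any object pixel
        grown = ndimage.binary_dilation(
            obj, structure=_disk_structure(expand_distance))
        neigh = np.unique(labels[grown])
        n_neighbors = len([x for x in neigh if x not in (0, k)])
        rows[int(k)] = [float(n_neighbors), float(near.mean())]
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"{prefix}_count", f"{prefix}_percent_touching"])


def _disk_structure(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2) <= radius ** 2
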