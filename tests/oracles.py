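"""Independent brute-force reference implementations used by the tests.

Each oracle recomputes a quantity from its definition with plain loops or a
different library path, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- intensity
def naive_intensity_stats(mask: np.ndarray, image: np.ndarray, label: int) -> dict:
    vals = []
    edge = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] != label:
                continue
            vals.append(image[r, c])
            on_border = False
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or mask[rr, cc] != label:
                    on_border = True
            if on_border:
                edge.append(image[r, c])
    v = np.array(vals, dtype=float)
    med = np.median(v)
    return {
        "integrated": v.sum(), "mean": v.mean(), "median": med,
        "std": v.std(), "mad": np.median(np.abs(v - med)),
        "min": v.min(), "max": v.max(),
        "q25": np.percentile(v, 25), "q75": np.percentile(v, 75),
        "edge_mean": np.mean(edge) if edge else v.mean(),
    }


# ------------------------------------------------------- radial distribution
def naive_radial(mask, image, label, n_rings=4, n_wedges=8):
    rs, cs = np.nonzero(mask == label)
    cy, cx = rs.mean(), cs.mean()
    dmax = max(math.hypot(r - cy, c - cx) for r, c in zip(rs, cs))
    ring_vals: list[list[float]] = [[] for _ in range(n_rings)]
    wedge_vals: dict[tuple[int, int], list[float]] = {}
    for r, c in zip(rs, cs):
        d = math.hypot(r - cy, c - cx)
        b = min(int((d / dmax if dmax > 0 else 0.0) * n_rings), n_rings - 1)
        theta = math.atan2(r - cy, c - cx)
        wdg = min(int((theta + math.pi) / (2 * math.pi) * n_wedges), n_wedges - 1)
        ring_vals[b].append(image[r, c])
        wedge_vals.setdefault((b, wdg), []).append(image[r, c])
    total = sum(sum(v) for v in ring_vals)
    n_px = len(rs)
    out = {}
    for b in range(n_rings):
        ring_sum = sum(ring_vals[b])
        frac = ring_sum / total if total > 0 else 0.0
        px_frac = len(ring_vals[b]) / n_px
        mean_frac = frac / px_frac if px_frac > 0 else 0.0
        means = [np.mean(wedge_vals[(b, w)]) for w in range(n_wedges)
                 if (b, w) in wedge_vals]
        cv = (np.std(means) / np.mean(means)
              if len(means) >= 2 and np.mean(means) != 0 else 0.0)
        out[b] = (frac, mean_frac, cv)
    return out


# ----------------------------------------------------------------- haralick
def naive_haralick(image, region, levels=8, offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1))):
    """13 Haralick features from explicit pair enumeration and the 1973
    formulas, averaged over the four directions."""
    vals = image[region]
    lo, hi = vals.min(), vals.max()
    h, w = image.shape
    q = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            if region[r, c] and hi > lo:
                q[r, c] = min(int((image[r, c] - lo) / (hi - lo) * levels),
                              levels - 1)
    per_direction = []
    for dr, dc in offsets:
        counts = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                rr, cc = r + dr, c + dc
                if (region[r, c] and 0 <= rr < h and 0 <= cc < w
                        and region[rr, cc]):
                    counts[q[r, c], q[rr, cc]] += 1
                    counts[q[rr, cc], q[r, c]] += 1
        if counts.sum() == 0:
            per_direction.append(np.zeros(13))
            continue
        p = counts / counts.sum()
        per_direction.append(_haralick13(p))
    return np.mean(per_direction, axis=0)


def _haralick13(p):
    g = p.shape[0]
    eps = np.finfo(float).tiny
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu = sum(i * px[i] for i in range(g))
    var = sum((i - mu) ** 2 * px[i] for i in range(g))
    asm = (p ** 2).sum()
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    corr = (sum((i - mu) * (j - mu) * p[i, j] for i in range(g) for j in range(g))
            / var) if var > 0 else 0.0
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    psum = np.zeros(2 * g - 1)
    pdiff = np.zeros(g)
    for i in range(g):
        for j in range(g):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    sum_avg = sum(k * psum[k] for k in range(2 * g - 1))
    sum_ent = -sum(psum[k] * math.log(psum[k] + eps) for k in range(2 * g - 1))
    sum_var = sum((k - sum_avg) ** 2 * psum[k] for k in range(2 * g - 1))
    entropy = -sum(p[i, j] * math.log(p[i, j] + eps)
                   for i in range(g) for j in range(g))
    diff_avg = sum(k * pdiff[k] for k in range(g))
    diff_var = sum((k - diff_avg) ** 2 * pdiff[k] for k in range(g))
    diff_ent = -sum(pdiff[k] * math.log(pdiff[k] + eps) for k in range(g))
    hx = -sum(px[i] * math.log(px[i] + eps) for i in range(g))
    hy = -sum(py[j] * math.log(py[j] + eps) for j in range(g))
    hxy1 = -sum(p[i, j] * math.log(px[i] * py[j] + eps)
                for i in range(g) for j in range(g))
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j] + eps)
                for i in range(g) for j in range(g))
    denom = max(hx, hy)
    im1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    im2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - entropy)), 0.0))
    return np.array([asm, contrast, corr, var, idm, sum_avg, sum_var, sum_ent,
                     entropy, diff_var, diff_ent, im1, im2])


# ---------------------------------------------------------------- neighbors
def naive_neighbors(labels, expand_distance):
    """O(n^2) boundary-distance neighbor counts and percent touching."""
    ids = sorted(set(labels.ravel()) - {0})
    h, w = labels.shape

    def boundary(k):
        pts = []
        for r in range(h):
            for c in range(w):
                if labels[r, c] != k:
                    continue
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or labels[rr, cc] != k:
                        pts.append((r, c))
                        break
        return pts

    all_px = {k: list(zip(*np.nonzero(labels == k))) for k in ids}
    out = {}
    for k in ids:
        bnd = boundary(k)
        neigh = set()
        touching = 0
        for br, bc in bnd:
            near = False
            for j in ids:
                if j == k:
                    continue
                for pr, pc in all_px[j]:
                    if math.hypot(br - pr, bc - pc) <= expand_distance:
                        neigh.add(j)
                        near = True
                        break
            if near:
                touching += 1
        # neighbor defn: any label within distance of any object pixel
        for j in ids:
            if j in neigh or j == k:
                continue
            done = False
            for pr, pc in all_px[k]:
                for qr, qc in all_px[j]:
                    if math.hypot(pr - qr, pc - qc) <= expand_distance:
                        neigh.add(j)
                        done = True
                        break
                if done:
                    break
        out[k] = (len(neigh), touching / len(bnd) if bnd else 0.0)
    return out


# -------------------------------------------------------------- granularity
def naive_granularity(image, n_scales):
    """Openings via explicit min/max loops over disk footprints."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    total = img.sum()
    if total <= 0:
        return np.zeros(n_scales)

    def opening(radius):
        offs = [(dr, dc) for dr in range(-radius, radius + 1)
                for dc in range(-radius, radius + 1)
                if abs(dr) + abs(dc) <= radius]
        ero = np.empty_like(img)
        for r in range(h):
            for c in range(w):
                m = np.inf
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    v = img[rr, cc] if 0 <= rr < h and 0 <= cc < w else np.inf
                    m = min(m, v)
                ero[r, c] = m
        dil = np.empty_like(img)
        for r in range(h):
            for c in range(w):
                m = -np.inf
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    v = ero[rr, cc] if 0 <= rr < h and 0 <= cc < w else -np.inf
                    m = max(m, v)
                dil[r, c] = m
        return dil

    prev = total
    out = np.zeros(n_scales)
    for i in range(1, n_scales + 1):
        vol = opening(i).sum()
        out[i - 1] = 100.0 * (prev - vol) / total
        prev = vol
    return np.maximum(out, 0.0)


# ------------------------------------------------------------- propagation
def dijkstra_propagation_oracle(seeds, guide, lambda_reg, foreground):
    """Seeded shortest-path assignment via scipy.sparse.csgraph.dijkstra."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra as cs_dijkstra

    h, w = guide.shape
    n = h * w
    adj = lil_matrix((n, n))
    for r in range(h):
        for c in range(w):
            if not foreground[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < h and cc < w and foreground[rr, cc]:
                    cost = math.sqrt((guide[r, c] - guide[rr, cc]) ** 2
                                     + lambda_reg ** 2)
                    adj[r * w + c, rr * w + cc] = cost
                    adj[rr * w + cc, r * w + c] = cost
    seed_nodes = [r * w + c for r, c in zip(*np.nonzero(seeds))]
    dist = cs_dijkstra(adj.tocsr(), directed=False, indices=seed_nodes)
    labels = np.zeros((h, w), dtype=int)
    seed_labels = [seeds[r, c] for r, c in zip(*np.nonzero(seeds))]
    for r in range(h):
        for c in range(w):
            if foreground[r, c]:
                d = dist[:, r * w + c]
                if np.isfinite(d).any():
                    labels[r, c] = seed_labels[int(np.argmin(d))]
    labels[seeds > 0] = seeds[seeds > 0]
    return labels


# --------------------------------------------------------------------- MI
def binned_mi(feature, y, bins=16):
    """Discrete plug-in MI estimate (nats) between a feature and labels."""
    edges = np.quantile(feature, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-9
    fx = np.searchsorted(edges, feature, side="right") - 1
    fx = np.clip(fx, 0, bins - 1)
    mi = 0.0
    n = len(y)
    for b in np.unique(fx):
        for c in np.unique(y):
            pxy = np.mean((fx == b) & (y == c))
            if pxy > 0:
                mi += pxy * math.log(pxy / (np.mean(fx == b) * np.mean(y == c)))
    return mi


# ------------------------------------------------------------------ zernike
def zernike_quadrature(binary, max_degree=9, sub=8):
    """Direct numerical integration of (n+1)/pi * <f, V_nm> on the unit disk
    (dense subpixel quadrature, plain projection)."""
    from math import factorial

    def radial(n, m, rho):
        out = np.zeros_like(rho)
        for s in range((n - m) // 2 + 1):
            coef = ((-1) ** s * factorial(n - s)
                    / (factorial(s) * factorial((n + m) // 2 - s)
                       * factorial((n - m) // 2 - s)))
            out = out + coef * rho ** (n - 2 * s)
        return out

    rr, cc = np.nonzero(binary)
    cy, cx = rr.mean(), cc.mean()
    radius = float(np.hypot(rr - cy, cc - cx).max())
    off = (np.arange(sub) + 0.5) / sub - 0.5
    oy, ox = np.meshgrid(off, off, indexing="ij")
    y = ((rr[:, None, None] + oy[None]) - cy) / radius
    x = ((cc[:, None, None] + ox[None]) - cx) / radius
    y, x = y.ravel(), x.ravel()
    rho = np.hypot(x, y)
    ins = rho <= 1
    rho, th = rho[ins], np.arctan2(y[ins], x[ins])
    dA = (1.0 / sub ** 2) / radius ** 2
    out = []
    for n in range(max_degree + 1):
        for m in range(n + 1):
            if (n - m) % 2:
                continue
            v = radial(n, m, rho) * np.exp(-1j * m * th)
            out.append(np.abs((n + 1) / np.pi * v.sum() * dA))
    return np.array(out)
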