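"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library routines the package itself uses:
region growing is a hand-rolled priority flood, convex hulls come from a
Jarvis march, statistics are direct formula evaluations with scalar
accumulation.
"""

from __future__ import annotations

import heapq
import math

import numpy as np
from scipy import ndimage


def priority_flood_regions(mask: np.ndarray, seeds: list[tuple[int, int]]) -> np.ndarray:
    """Watershed-style region growing on the Euclidean distance map.

    Pixels are flooded in order of decreasing distance-to-background,
    starting from the given seed pixels (seed i gets label i+1), each new
    pixel joining the region of the neighbour that reached it first.
    """
    mask = np.asarray(mask, dtype=bool)
    dist = ndimage.distance_transform_edt(mask)
    labels = np.zeros(mask.shape, dtype=np.int32)
    heap = []
    order = 0
    for i, (r, c) in enumerate(seeds, start=1):
        labels[r, c] = i
        heapq.heappush(heap, (-dist[r, c], order, r, c))
        order += 1
    h, w = mask.shape
    while heap:
        _, _, r, c = heapq.heappop(heap)
        lab = labels[r, c]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                    labels[rr, cc] = lab
                    heapq.heappush(heap, (-dist[rr, cc], order, rr, cc))
                    order += 1
    return labels


def jarvis_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices (counter-clockwise) by gift wrapping."""
    pts = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    n = len(pts)
    if n < 3:
        return pts
    start = min(range(n), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % n
        for r in range(n):
            u = pts[q] - pts[p]
            v = pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.dot(pts[r] - pts[p], pts[r] - pts[p]) >
                             np.dot(pts[q] - pts[p], pts[q] - pts[p])):
                q = r
        if q == start:
            break
        hull.append(q)
    return pts[hull]


def hull_pixel_count(rows: np.ndarray, cols: np.ndarray, tol: float = 1e-9) -> int:
    """Grid points inside (or on) the convex hull of the pixel centres."""
    pts = np.column_stack([rows, cols]).astype(np.float64)
    verts = jarvis_hull(pts)
    if len(verts) < 3:
        return len(np.unique(pts, axis=0))
    rr, cc = np.mgrid[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    inside = np.ones(len(grid), dtype=bool)
    m = len(verts)
    for i in range(m):
        a, b = verts[i], verts[(i + 1) % m]
        edge = b - a
        # CCW polygon: interior is to the left of each edge
        cross = edge[0] * (grid[:, 1] - a[1]) - edge[1] * (grid[:, 0] - a[0])
        inside &= cross >= -tol
    return int(inside.sum())


def solidity_oracle(rows, cols) -> float:
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    return rows.size / hull_pixel_count(rows, cols)


def flood_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill holes via BFS of background from the border (4-connected)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    outside = np.zeros((h, w), dtype=bool)
    stack = [(r, c) for r in range(h) for c in (0, w - 1) if not mask[r, c]]
    stack += [(r, c) for c in range(w) for r in (0, h - 1) if not mask[r, c]]
    for r, c in stack:
        outside[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                stack.append((rr, cc))
    return ~outside | mask


def bland_altman_oracle(manual, automated) -> dict:
    """Direct-formula Bland–Altman with scalar accumulation."""
    from scipy import stats

    d = [a - m for a, m in zip(automated, manual)]
    n = len(d)
    bias = math.fsum(d) / n
    var = math.fsum((x - bias) ** 2 for x in d) / (n - 1)
    sd = math.sqrt(var)
    tcrit = stats.t.ppf(0.975, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    loa_lo = bias - 1.96 * sd
    loa_hi = bias + 1.96 * sd
    return {
        "bias": bias,
        "sd": sd,
        "loa_lower": loa_lo,
        "loa_upper": loa_hi,
        "bias_ci": (bias - tcrit * se_bias, bias + tcrit * se_bias),
        "loa_lower_ci": (loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        "loa_upper_ci": (loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
        "n_outside": sum(1 for x in d if x < loa_lo or x > loa_hi),
    }


def paired_t_oracle(manual, automated) -> tuple[float, float]:
    from scipy import stats

    d = [a - m for a, m in zip(automated, manual)]
    n = len(d)
    mean = math.fsum(d) / n
    sd = math.sqrt(math.fsum((x - mean) ** 2 for x in d) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    return t, 2.0 * stats.t.sf(abs(t), n - 1)


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    cov = math.fsum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = math.fsum((a - mx) ** 2 for a in x)
    vy = math.fsum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)
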