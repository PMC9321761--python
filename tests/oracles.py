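"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration, deliberately
avoiding the vectorised/recursive machinery of the package under test.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def brute_median(arr: np.ndarray, width: int) -> np.ndarray:
    """Median filter by explicit neighbourhood sort, reflect padding."""
    r = width // 2
    padded = np.pad(arr, r, mode="symmetric")
    out = np.empty_like(arr)
    for x in range(arr.shape[0]):
        for y in range(arr.shape[1]):
            for z in range(arr.shape[2]):
                nb = padded[x : x + width, y : y + width, z : z + width]
                out[x, y, z] = np.median(np.sort(nb.ravel()))
    return out


def brute_otsu_argmax(arr: np.ndarray) -> set[int]:
    """All thresholds maximising between-class variance (exhaustive search)."""
    n_levels = 256 if arr.dtype == np.uint8 else 65536
    flat = arr.ravel().astype(np.float64)
    best = -1.0
    winners: set[int] = set()
    for t in range(n_levels):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if var > best + 1e-9:
            best = var
            winners = {t}
        elif abs(var - best) <= 1e-9:
            winners.add(t)
    return winners


def brute_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Erosion by testing the structuring element at every voxel (reflect pad)."""
    r = footprint.shape[0] // 2
    padded = np.pad(mask, r, mode="symmetric")
    out = np.zeros_like(mask)
    for x in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for z in range(mask.shape[2]):
                nb = padded[x : x + footprint.shape[0], y : y + footprint.shape[1], z : z + footprint.shape[2]]
                out[x, y, z] = bool(np.all(nb[footprint]))
    return out


_OFF = {
    6: [o for o in product((-1, 0, 1), repeat=3) if sum(abs(v) for v in o) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3) if 0 < sum(abs(v) for v in o) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
}


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels via BFS from each unvisited voxel."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    nxt = 0
    offs = _OFF[connectivity]
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        nxt += 1
        stack = [seed]
        labels[seed] = nxt
        while stack:
            c = stack.pop()
            for o in offs:
                n = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
                if all(0 <= n[k] < mask.shape[k] for k in range(3)):
                    if mask[n] and not labels[n]:
                        labels[n] = nxt
                        stack.append(n)
    return labels


def euler_by_enumeration(mask: np.ndarray) -> int:
    """chi = V - E + F - C of the closed-voxel complex, by enumerating the
    vertex/edge/face/cube sets of every object voxel explicitly."""
    vertices: set = set()
    edges: set = set()
    faces: set = set()
    cubes: set = set()
    for x, y, z in zip(*np.nonzero(mask)):
        x, y, z = int(x), int(y), int(z)
        cubes.add((x, y, z))
        corners = [(x + i, y + j, z + k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        vertices.update(corners)
        for a, b in product(corners, corners):
            if a < b and sum(abs(a[t] - b[t]) for t in range(3)) == 1:
                edges.add((a, b))
        for axis in range(3):
            for side in (0, 1):
                quad = tuple(sorted(c for c in corners if c[axis] == (x, y, z)[axis] + side))
                faces.add((axis,) + quad)
    return len(vertices) - len(edges) + len(faces) - len(cubes)


def brute_edt(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest background voxel, all pairs."""
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=np.float64)
    for c in np.argwhere(mask):
        out[tuple(c)] = np.sqrt(((bg - c) ** 2).sum(axis=1).min())
    return out


def kmeans_1d_optimal_wcss(levels: np.ndarray, counts: np.ndarray, k: int) -> float:
    """Exact optimal 1-D k-means objective by dynamic programming over the
    sorted levels (contiguity of optimal 1-D clusters)."""
    order = np.argsort(levels)
    v = levels[order].astype(np.float64)
    w = counts[order].astype(np.float64)
    n = v.size
    # prefix sums for O(1) interval cost
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwv = np.concatenate([[0.0], np.cumsum(w * v)])
    cwv2 = np.concatenate([[0.0], np.cumsum(w * v * v)])

    def cost(i, j):  # interval [i, j)
        ww = cw[j] - cw[i]
        if ww == 0:
            return 0.0
        s = cwv[j] - cwv[i]
        s2 = cwv2[j] - cwv2[i]
        return s2 - s * s / ww

    inf = float("inf")
    dp = [[inf] * (n + 1) for _ in range(k + 1)]
    dp[0][0] = 0.0
    for kk in range(1, k + 1):
        for j in range(1, n + 1):
            for i in range(kk - 1, j):
                c = dp[kk - 1][i] + cost(i, j)
                if c < dp[kk][j]:
                    dp[kk][j] = c
    return dp[k][n]


def diamond_ring(shape, center, r, z=1) -> np.ndarray:
    """Closed unit-width ring: Manhattan circle, clean under 26-adjacency."""
    m = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            if abs(i - center[0]) + abs(j - center[1]) == r:
                m[i, j, z] = True
    return m
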