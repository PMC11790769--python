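"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the implementation's algorithms: DTW is checked by
exhaustively enumerating every monotone warping path, and hierarchical
clustering by a naive agglomerative loop applying the textbook
Lance-Williams update formulas to explicit cluster sets.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_dtw(cost: np.ndarray) -> float:
    """Minimum total cost over ALL monotone warping paths (exponential search).

    Paths start at (0, 0), end at (n-1, m-1), and move by (1,0), (0,1) or
    (1,1).  Feasible only for tiny matrices.
    """
    n, m = cost.shape
    best = [math.inf]

    def walk(i: int, j: int, total: float) -> None:
        total += cost[i, j]
        if total >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = total
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, total)
        if i + 1 < n:
            walk(i + 1, j, total)
        if j + 1 < m:
            walk(i, j + 1, total)

    walk(0, 0, 0.0)
    return best[0]


def pairwise_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.ndim == 1:
        return np.abs(a[:, None] - b[None, :])
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


# ---------------------------------------------------------------------------

def _lw_update(method: str, d_uw, d_vw, d_uv, nu, nv, nw):
    """Post-merge distance d(u+v, w) by the textbook formula for each linkage."""
    if method == "single":
        return min(d_uw, d_vw)
    if method == "complete":
        return max(d_uw, d_vw)
    if method == "average":
        return (nu * d_uw + nv * d_vw) / (nu + nv)
    if method == "ward":
        t = nu + nv + nw
        val = ((nu + nw) * d_uw**2 + (nv + nw) * d_vw**2 - nw * d_uv**2) / t
        return math.sqrt(max(val, 0.0))
    if method == "centroid":
        s = nu + nv
        val = (nu * d_uw**2 + nv * d_vw**2) / s - nu * nv * d_uv**2 / s**2
        return math.sqrt(max(val, 0.0))
    raise ValueError(method)


def agglomerate(D: np.ndarray, method: str) -> np.ndarray:
    """Naive greedy agglomeration; returns the cophenetic distance matrix.

    At each step the closest cluster pair merges at its current distance;
    the cophenetic matrix records, for every leaf pair, the height of the
    merge that first united them.  Comparing cophenetic matrices makes the
    check insensitive to merge-order bookkeeping.
    """
    n = len(D)
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (u, v), h = min(dist.items(), key=lambda kv: kv[1])
        for a in clusters[u]:
            for b in clusters[v]:
                coph[a, b] = coph[b, a] = h
        merged = clusters[u] | clusters[v]
        nu, nv = len(clusters[u]), len(clusters[v])
        del clusters[u], clusters[v]
        new_dist = {}
        for (a, b), d in dist.items():
            if u in (a, b) or v in (a, b):
                continue
            new_dist[(a, b)] = d
        for w, members in clusters.items():
            key_uw = (min(u, w), max(u, w))
            key_vw = (min(v, w), max(v, w))
            new_dist[(w, next_id)] = _lw_update(
                method, dist[key_uw], dist[key_vw], h, nu, nv, len(members)
            )
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return coph
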