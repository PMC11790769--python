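"""Trajectory clustering: DTW dissimilarities, MDS embedding, silhouette-guided k-means.

The pipeline mirrors common practice for comparing open-field paths across
subjects: clip every track to the same time window (typically the first 30 s
after placement), map each arena onto the unit square so arenas of different
sizes become comparable, compute all pairwise dynamic-time-warping (DTW)
distances, embed the dissimilarity matrix into the plane with metric MDS,
and run k-means there with the number of clusters chosen by the mean
silhouette score.  Each cluster is also summarized by its medoid in the
original DTW metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score

from .tracking import Track


@dataclass
class Trajectory:
    """A subject's path over a fixed window, in normalized arena units [0,1]^2."""

    subject_id: str
    points: np.ndarray  # (n, 2)
    window: tuple[float, float]  # (start_s, duration_s)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("a trajectory needs >= 2 (x, y) points")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise DTW distances among subjects."""

    subjects: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.subjects)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match subject count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.subjects, columns=self.subjects)


@dataclass
class TrajClusterResult:
    k: int
    labels: np.ndarray
    silhouette_by_k: dict[int, float]
    coords: np.ndarray  # (n, dims) MDS embedding
    stress: float
    centroids: np.ndarray  # (k, dims) k-means centroids in MDS space
    medoids: dict[int, int]  # cluster -> subject index of medoid (DTW metric)


def clip_window(track: Track, start_s: float, duration_s: float) -> np.ndarray:
    """Samples with start_s <= t < start_s + duration_s (t relative to track start)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    t = track.times_s
    sel = (t >= start_s) & (t < start_s + duration_s)
    if not sel.any():
        raise ValueError(f"window [{start_s}, {start_s + duration_s}) s is outside the track")
    return track.samples[sel]


def normalize_trajectory(
    points_px: np.ndarray,
    arena_rect: tuple[float, float, float, float],
    subject_id: str = "",
    window: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Map arena pixel coordinates onto the unit square (per-axis affine)."""
    x0, y0, x1, y1 = arena_rect
    w, h = x1 - x0, y1 - y0
    if w <= 0 or h <= 0:
        raise ValueError("degenerate arena rectangle")
    pts = np.asarray(points_px, dtype=float)
    out = np.column_stack([(pts[:, 0] - x0) / w, (pts[:, 1] - y0) / h])
    if out.min() < -1e-9 or out.max() > 1 + 1e-9:
        raise ValueError("points fall outside the arena rectangle")
    return Trajectory(subject_id=subject_id, points=np.clip(out, 0.0, 1.0), window=window)


def _local_cost(a: np.ndarray, b: np.ndarray, local_cost: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sequence")
    if local_cost == "euclidean2d":
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("euclidean2d expects (n, d) sequences")
        return cdist(a, b)
    if local_cost == "absdiff1d":
        return np.abs(a.reshape(-1, 1) - b.reshape(1, -1))
    raise ValueError(f"unknown local cost {local_cost!r}")


def dtw_distance(
    seq_a,
    seq_b,
    local_cost: str = "euclidean2d",
    band: int | None = None,
) -> tuple[float, np.ndarray]:
    """Classic unnormalized DTW distance plus the full accumulated cost matrix.

    D[i, j] = cost(i, j) + min(D[i-1, j], D[i, j-1], D[i-1, j-1]) with
    D[0, 0] = cost(0, 0); the reported distance is D[n-1, m-1].  ``band`` is
    an optional Sakoe-Chiba radius restricting |i - j|.

    The DP is evaluated along anti-diagonals, which vectorizes the recursion
    without compiled extensions.
    """
    C = _local_cost(seq_a, seq_b, local_cost)
    n, m = C.shape
    if band is not None:
        i, j = np.ogrid[:n, :m]
        C = np.where(np.abs(i - j) <= band, C, np.inf)
    D = np.full((n + 1, m + 1), np.inf)
    D[1, 1] = C[0, 0]
    for d in range(3, n + m + 1):  # d = i + j in 1-based padded coordinates
        i = np.arange(max(1, d - m), min(n, d - 1) + 1)
        j = d - i
        prev = np.minimum(np.minimum(D[i - 1, j], D[i, j - 1]), D[i - 1, j - 1])
        D[i, j] = C[i - 1, j - 1] + prev
    acc = D[1:, 1:]
    return float(acc[-1, -1]), acc


def dissimilarity_matrix(
    trajectories: list[Trajectory] | list[np.ndarray],
    local_cost: str = "euclidean2d",
    band: int | None = None,
) -> DissimilarityMatrix:
    """All pairwise DTW distances among trajectories (or raw series)."""
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    seqs, subjects = [], []
    for i, t in enumerate(trajectories):
        if isinstance(t, Trajectory):
            seqs.append(t.points)
            subjects.append(t.subject_id or str(i))
        else:
            seqs.append(np.asarray(t, dtype=float))
            subjects.append(str(i))
    n = len(seqs)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = dtw_distance(seqs[i], seqs[j], local_cost=local_cost, band=band)
            M[i, j] = M[j, i] = d
    return DissimilarityMatrix(subjects=subjects, matrix=M)


def mds_embed(
    matrix: DissimilarityMatrix | np.ndarray, dims: int = 2, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Metric MDS of a dissimilarity matrix (SMACOF, classical-scaling init)."""
    M = matrix.matrix if isinstance(matrix, DissimilarityMatrix) else np.asarray(matrix, float)
    if not np.allclose(M, 0.0):
        mds = MDS(
            n_components=dims,
            metric="precomputed",
            init="classical_mds",
            random_state=seed,
            max_iter=1000,
            eps=1e-9,
            normalized_stress=False,
        )
        coords = mds.fit_transform(M)
        return coords, float(mds.stress_)
    return np.zeros((len(M), dims)), 0.0


def select_k_and_cluster(
    coords: np.ndarray,
    dtw_matrix: DissimilarityMatrix | np.ndarray | None = None,
    k_range: range | None = None,
    seed: int = 0,
    stress: float = 0.0,
) -> TrajClusterResult:
    """Seeded k-means on the MDS coordinates with silhouette-selected k.

    For every k in ``k_range`` (default 2..min(n-1, 10)) k-means is run with
    10 restarts and the mean silhouette score computed on the same
    coordinates; the k maximizing it wins, ties going to the smaller k.
    When the DTW matrix is supplied, each cluster's medoid (member with the
    smallest summed DTW distance to its co-members) is reported as the
    cluster representative.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 subjects to scan k >= 2")
    if k_range is None:
        k_range = range(2, min(n - 1, 10) + 1)
    scores: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(coords)
        scores[k] = float(silhouette_score(coords, lab))
        fits[k] = km
    best_k = max(sorted(scores), key=lambda k: scores[k])  # ties -> smaller k
    labels = fits[best_k].labels_

    medoids: dict[int, int] = {}
    if dtw_matrix is not None:
        M = dtw_matrix.matrix if isinstance(dtw_matrix, DissimilarityMatrix) else np.asarray(dtw_matrix)
        for c in range(best_k):
            members = np.flatnonzero(labels == c)
            within = M[np.ix_(members, members)].sum(axis=1)
            medoids[c] = int(members[np.argmin(within)])
    return TrajClusterResult(
        k=best_k,
        labels=labels,
        silhouette_by_k=scores,
        coords=coords,
        stress=stress,
        centroids=fits[best_k].cluster_centers_,
        medoids=medoids,
    )


def cluster_trajectories(
    trajectories: list[Trajectory] | list[np.ndarray],
    k_range: range | None = None,
    dims: int = 2,
    seed: int = 0,
    local_cost: str = "euclidean2d",
) -> tuple[DissimilarityMatrix, TrajClusterResult]:
    """DTW matrix -> MDS -> silhouette-selected k-means, in one call."""
    dmat = dissimilarity_matrix(trajectories, local_cost=local_cost)
    coords, stress = mds_embed(dmat, dims=dims, seed=seed)
    result = select_k_and_cluster(coords, dtw_matrix=dmat, k_range=k_range, seed=seed, stress=stress)
    return dmat, result
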