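"""Heading-angle analysis: smoothing, DTW dissimilarity, hierarchical clustering.

A subject's locomotion is reduced to a heading-angle time series (direction
of the frame-to-frame displacement, in degrees), which is unwrapped to a
continuous curve so that crossings of the ±180° cut do not create artificial
jumps.  Subjects are compared by DTW with absolute-difference local cost and
grouped by agglomerative hierarchical clustering (Ward by default, the other
classic linkages available); a dendrogram cutoff height turns the hierarchy
into flat clusters.  Clusters are summarized by pointwise mean ± SD angle
profiles, and pairs of clusters are contrasted through the accumulated DTW
cost matrix between their mean curves — the bottom-right cell being the
between-cluster distance (larger = less similar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .trajcluster import DissimilarityMatrix, dtw_distance

LINKAGE_METHODS = ("ward", "single", "complete", "average", "centroid")


@dataclass
class AngleSeries:
    """Unwrapped heading angles (degrees) for one subject."""

    subject_id: str
    values: np.ndarray
    fps: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("an angle series needs >= 2 values")
        if not np.isfinite(self.values).all():
            raise ValueError("angle series must be finite")

    def wrapped(self) -> np.ndarray:
        """Raw headings in (-180, 180], recovered from the unwrapped curve."""
        w = np.mod(self.values, 360.0)
        return np.where(w > 180.0, w - 360.0, w)


@dataclass
class HierarchyResult:
    """An agglomerative merge tree plus the flat clustering at a cutoff."""

    method: str
    merges: np.ndarray  # scipy linkage matrix, (n-1, 4)
    cutoff_height: float
    labels: np.ndarray  # 0-based, in order of first appearance

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class ClusterProfile:
    """Pointwise mean ± SD angle curve of one cluster (population SD)."""

    cluster_id: int
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have equal length")


def heading_series(
    points: np.ndarray,
    min_step_px: float = 0.0,
    fps: float = 1.0,
    subject_id: str = "",
) -> AngleSeries:
    """Heading of each displacement, unwrapped to a continuous curve.

    The heading of displacement (dx, dy) is the angle of (dx, -dy): the
    y-axis is flipped so angles are counterclockwise-positive with 0° =
    rightward, matching the usual mathematical convention on screen
    coordinates (y down).  Displacements shorter than ``min_step_px`` reuse
    the previous heading (jitter below the tracker's resolution carries no
    directional information); leading short steps take the first defined
    heading.  The result is unwrapped: ±360° multiples are added so that
    successive differences lie in (-180°, 180°].
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (x, y) points")
    d = np.diff(pts, axis=0)
    step = np.hypot(d[:, 0], d[:, 1])
    moving = step >= max(min_step_px, 1e-300)
    if not moving.any():
        raise ValueError("all displacements below min_step_px: heading undefined")
    raw = np.degrees(np.arctan2(-d[:, 1], d[:, 0]))
    # carry the last defined heading through sub-threshold steps
    idx = np.where(moving, np.arange(len(raw)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(moving)
    idx[idx < 0] = first
    held = raw[idx]
    unwrapped = np.unwrap(held, period=360.0)
    return AngleSeries(subject_id=subject_id, values=unwrapped, fps=fps)


def gaussian_kernel(kernel_size: int) -> np.ndarray:
    """Normalized discrete Gaussian of window length 2k+1 with sigma = k/2."""
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    sigma = kernel_size / 2.0
    x = np.arange(-kernel_size, kernel_size + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(series: AngleSeries, kernel_size: int) -> AngleSeries:
    """Smooth an angle series with a normalized Gaussian window.

    Window length is 2·kernel_size+1 with sigma = kernel_size/2; reflect
    padding keeps the output length equal to the input length.  Smoothing
    happens on the unwrapped curve, so wrap-around artifacts cannot occur.
    """
    v = series.values
    if len(v) < 2:
        raise ValueError("series too short to smooth")
    w = gaussian_kernel(kernel_size)
    padded = np.pad(v, kernel_size, mode="reflect")
    out = np.convolve(padded, w, mode="valid")
    return AngleSeries(subject_id=series.subject_id, values=out, fps=series.fps)


def angle_dissimilarity_matrix(
    series_list: list[AngleSeries] | list[np.ndarray], band: int | None = None
) -> DissimilarityMatrix:
    """Pairwise DTW (absolute-difference cost) among unwrapped angle series."""
    if len(series_list) < 2:
        raise ValueError("need at least 2 series")
    seqs, subjects = [], []
    for i, s in enumerate(series_list):
        if isinstance(s, AngleSeries):
            seqs.append(s.values)
            subjects.append(s.subject_id or str(i))
        else:
            seqs.append(np.asarray(s, dtype=float))
            subjects.append(str(i))
    n = len(seqs)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = dtw_distance(seqs[i], seqs[j], local_cost="absdiff1d", band=band)
            M[i, j] = M[j, i] = d
    return DissimilarityMatrix(subjects=subjects, matrix=M)


def _relabel_first_appearance(raw: np.ndarray) -> np.ndarray:
    out = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def hierarchical_cluster(
    matrix: DissimilarityMatrix | np.ndarray,
    method: str = "ward",
    cutoff_height: float | None = None,
) -> HierarchyResult:
    """Agglomerative clustering of a dissimilarity matrix.

    Merging follows the Lance–Williams recurrences on the supplied
    distances (Ward, single, complete, average, centroid).  Ward and
    centroid formally assume squared-Euclidean input; applying them to DTW
    distances is the field's common practice and is kept here, documented
    as a caveat.  Flat labels are the connected components after removing
    merges higher than ``cutoff_height`` (defaults to the top merge height,
    i.e. one cluster).
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}")
    M = matrix.matrix if isinstance(matrix, DissimilarityMatrix) else np.asarray(matrix, float)
    Z = linkage(squareform(M, checks=False), method=method)
    if cutoff_height is None:
        cutoff_height = float(Z[-1, 2])
    raw = fcluster(Z, t=cutoff_height, criterion="distance")
    return HierarchyResult(
        method=method,
        merges=Z,
        cutoff_height=float(cutoff_height),
        labels=_relabel_first_appearance(raw),
    )


def cutoff_for_k(merges: np.ndarray, k: int) -> float:
    """A cutoff height that yields exactly k flat clusters (monotone linkages).

    Midpoint between the merge heights bracketing the k-cluster regime —
    the programmatic equivalent of eyeballing a dendrogram and drawing the
    cutoff line between well-separated merge levels.
    """
    heights = np.sort(merges[:, 2])
    n = len(merges) + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    if k == 1:
        return float(heights[-1])
    if k == n:
        return float(heights[0]) / 2.0
    hi = heights[n - k]  # height of the merge that reduces k clusters to k-1
    lo = heights[n - k - 1]
    return float((lo + hi) / 2.0)


def cluster_mean_profile(
    series_list: list[AngleSeries] | list[np.ndarray],
    labels: np.ndarray,
    resample_length: int | None = None,
) -> list[ClusterProfile]:
    """Mean ± SD angle curve per cluster, members resampled to a common length.

    The target length defaults to the shortest member; resampling is linear
    on the unwrapped curves; SD is the population SD (singleton clusters get
    SD ≡ 0).
    """
    values = [s.values if isinstance(s, AngleSeries) else np.asarray(s, float) for s in series_list]
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("series and labels length mismatch")
    L = resample_length if resample_length is not None else min(len(v) for v in values)
    grid = np.linspace(0.0, 1.0, L)
    profiles = []
    for c in np.unique(labels):
        members = [values[i] for i in np.flatnonzero(labels == c)]
        if not members:
            raise ValueError(f"cluster {c} is empty")
        R = np.stack([np.interp(grid, np.linspace(0, 1, len(v)), v) for v in members])
        profiles.append(ClusterProfile(cluster_id=int(c), mean=R.mean(axis=0), sd=R.std(axis=0)))
    return profiles


def cluster_cost_matrix(
    profile_a: ClusterProfile, profile_b: ClusterProfile
) -> tuple[np.ndarray, float]:
    """Accumulated DTW cost matrix between two cluster mean curves.

    Returns (matrix, distance): the full DP table with absolute-difference
    local cost, whose bottom-right cell is the between-cluster distance.
    """
    d, acc = dtw_distance(profile_a.mean, profile_b.mean, local_cost="absdiff1d")
    return acc, d


def profiles_to_frame(profiles: list[ClusterProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, (m, s) in enumerate(zip(p.mean, p.sd)):
            rows.append((p.cluster_id, t, m, s))
    return pd.DataFrame(rows, columns=["cluster", "t", "mean_deg", "sd_deg"])
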