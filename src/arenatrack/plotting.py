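"""Figure panels for the standard reports.

Functional equivalents of the usual report graphics: trajectory plot and
occupancy heatmap per arena, DTW-distance heatmap ordered by a dendrogram,
silhouette-vs-k curve, MDS scatter with k-means centroids, per-cluster
trajectory panels, dendrogram with cutoff line, cluster mean-angle profiles
with SD bands, and accumulated-cost-matrix heatmaps.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform

from .anglecluster import ClusterProfile, HierarchyResult
from .trajcluster import DissimilarityMatrix, Trajectory, TrajClusterResult


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory(points: np.ndarray, arena_rect, path) -> None:
    x0, y0, x1, y1 = arena_rect
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(points[:, 0], points[:, 1], lw=0.8)
    ax.set_xlim(x0, x1)
    ax.set_ylim(y1, y0)  # y down, image convention
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title("trajectory")
    _save(fig, path)


def plot_heatmap(grid: np.ndarray, path, title: str = "occupancy") -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(grid.T, origin="upper", cmap="hot")
    fig.colorbar(im, ax=ax, label="frames")
    ax.set_title(title)
    _save(fig, path)


def plot_distance_heatmap(dmat: DissimilarityMatrix, path) -> None:
    """Distance heatmap with rows/columns ordered by an average-linkage dendrogram."""
    M = dmat.matrix
    if len(M) > 2:
        Z = linkage(squareform(M, checks=False), method="average")
        order = dendrogram(Z, no_plot=True)["leaves"]
    else:
        order = list(range(len(M)))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M[np.ix_(order, order)], cmap="viridis")
    fig.colorbar(im, ax=ax, label="DTW distance")
    labels = [dmat.subjects[i] for i in order]
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.set_title("pairwise DTW dissimilarity")
    _save(fig, path)


def plot_silhouette_curve(silhouette_by_k: dict[int, float], chosen_k: int, path) -> None:
    ks = sorted(silhouette_by_k)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ks, [silhouette_by_k[k] for k in ks], "o-")
    ax.axvline(chosen_k, color="red", ls="--", label=f"chosen k = {chosen_k}")
    ax.set_xlabel("k")
    ax.set_ylabel("mean silhouette")
    ax.legend()
    _save(fig, path)


def plot_mds_clusters(result: TrajClusterResult, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for c in range(result.k):
        sel = result.labels == c
        ax.scatter(result.coords[sel, 0], result.coords[sel, 1], s=30, label=f"cluster {c}")
    ax.scatter(
        result.centroids[:, 0], result.centroids[:, 1],
        marker="X", s=120, c="black", label="centroids",
    )
    ax.set_title(f"MDS embedding (stress {result.stress:.3g})")
    ax.legend(fontsize=7)
    _save(fig, path)


def plot_cluster_trajectories(
    trajectories: list[Trajectory], labels: np.ndarray, path_prefix
) -> list[Path]:
    paths = []
    for c in np.unique(labels):
        fig, ax = plt.subplots(figsize=(4, 4))
        for i in np.flatnonzero(labels == c):
            pts = trajectories[i].points
            ax.plot(pts[:, 0], pts[:, 1], lw=0.8, alpha=0.8)
        ax.set_xlim(0, 1)
        ax.set_ylim(1, 0)
        ax.set_aspect("equal")
        ax.set_title(f"cluster {c}")
        p = Path(f"{path_prefix}_cluster{c}.png")
        _save(fig, p)
        paths.append(p)
    return paths


def plot_dendrogram(result: HierarchyResult, subjects: list[str], path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    dendrogram(result.merges, labels=subjects, ax=ax, color_threshold=result.cutoff_height)
    ax.axhline(result.cutoff_height, color="red", ls="--", label=f"cutoff = {result.cutoff_height:g}")
    ax.set_ylabel("merge height (DTW distance)")
    ax.legend()
    _save(fig, path)


def plot_profiles(profiles: list[ClusterProfile], path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        t = np.arange(len(p.mean))
        (line,) = ax.plot(t, p.mean, label=f"cluster {p.cluster_id}")
        ax.fill_between(t, p.mean - p.sd, p.mean + p.sd, alpha=0.25, color=line.get_color())
    ax.set_xlabel("resampled time index")
    ax.set_ylabel("angle (deg, unwrapped)")
    ax.legend()
    _save(fig, path)


def plot_cost_matrix(acc: np.ndarray, path, title: str = "accumulated DTW cost") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(acc, origin="lower", cmap="magma", aspect="auto")
    fig.colorbar(im, ax=ax, label="accumulated cost")
    ax.set_title(f"{title} (distance {acc[-1, -1]:.1f})")
    _save(fig, path)
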