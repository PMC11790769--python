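"""Ground-truthed synthetic fixtures: arena videos, trajectories, angle series.

The renderer emulates the standard behavior-recording scene: a static bright
background containing up to four disjoint rectangular arenas, one dark
elliptical animal blob per arena following a scripted polyline path, optional
per-pixel Gaussian sensor noise, and an animal-free "leader" segment at the
start of the recording (real protocols record a few seconds of empty arena so
a clean background frame can be taken).  Because the path is scripted, every
downstream quantity — per-frame centroid, total path length, zone occupancy —
has an analytic ground truth.

Population generators plant known cluster structure into collections of 2-D
trajectories or 1-D heading-angle series so that the clustering pipelines can
be tested for planted-label recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .videoio import write_video

Rect = tuple[float, float, float, float]  # (x0, y0, x1, y1) in px, x right / y down

MAX_ARENAS = 4


@dataclass(frozen=True)
class ScriptedPath:
    """A polyline path sampled at constant speed over a fixed duration."""

    waypoints: tuple[tuple[float, float], ...]
    duration_s: float
    fps: float
    interpolation: str = "linear"

    def __post_init__(self):
        object.__setattr__(self, "waypoints", tuple((float(x), float(y)) for x, y in self.waypoints))
        if len(self.waypoints) < 1:
            raise ValueError("ScriptedPath needs at least one waypoint")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.interpolation != "linear":
            raise ValueError(f"unsupported interpolation {self.interpolation!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def length_px(self) -> float:
        """Analytic polyline length."""
        pts = np.asarray(self.waypoints, dtype=float)
        if len(pts) == 1:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, photometry and noise of a synthetic recording."""

    frame_size: tuple[int, int] = (320, 240)  # (width, height)
    background_level: int = 230
    arenas: tuple[Rect, ...] = ((10.0, 10.0, 150.0, 110.0),)
    blob: tuple[float, float, int] = (14.0, 8.0, 20)  # major_px, minor_px, intensity
    noise_sigma: float = 0.0
    seed: int = 0
    leader_s: float = 2.0  # animal-free lead-in, seconds

    def __post_init__(self):
        if not 1 <= len(self.arenas) <= MAX_ARENAS:
            raise ValueError(f"number of arenas must be 1..{MAX_ARENAS}, got {len(self.arenas)}")
        if self.blob[2] == self.background_level:
            raise ValueError("blob intensity must differ from background_level")
        for i, a in enumerate(self.arenas):
            for b in self.arenas[i + 1:]:
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ValueError("arenas must be pairwise disjoint")


@dataclass
class GroundTruth:
    """Per-frame true centroids and analytic path lengths, per arena."""

    first_frame: int  # index of the first frame containing a blob
    positions: dict[int, np.ndarray]  # arena_id -> (n_frames, 2) array of (x, y)
    path_length_px: dict[int, float]
    fps: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arena, pos in self.positions.items():
            for i, (x, y) in enumerate(pos):
                rows.append((self.first_frame + i, arena, x, y))
        return pd.DataFrame(rows, columns=["frame", "arena", "x_px", "y_px"])

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def make_scripted_track(path: ScriptedPath) -> np.ndarray:
    """Sample a scripted path at its frame rate.

    Returns a ``(round(duration_s * fps), 2)`` array of positions spaced
    uniformly in arc length over time (constant speed along the polyline);
    the first and last samples coincide with the first and last waypoints.
    """
    n = path.n_frames
    pts = np.asarray(path.waypoints, dtype=float)
    if len(pts) == 1 or path.length_px == 0.0:
        return np.tile(pts[0], (n, 1))
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.linspace(0.0, cum[-1], n) if n > 1 else np.array([0.0])
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])


def _contains(rect: Rect, xy: np.ndarray) -> np.ndarray:
    x0, y0, x1, y1 = rect
    return (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)


def render_video(
    scene: SceneSpec,
    paths: dict[int, ScriptedPath],
    out_path: str | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic recording and its ground truth.

    ``paths`` maps arena index (into ``scene.arenas``) to a scripted path;
    all paths must share one frame rate and stay inside their arena.  The
    first ``round(scene.leader_s * fps)`` frames are blob-free so background
    estimation from the leader is exercised.  Noise is i.i.d. Gaussian per
    pixel with the scene seed, clipped to [0, 255]; rendering is therefore
    byte-deterministic under a fixed spec.
    """
    if not paths:
        raise ValueError("at least one arena must have a path")
    fps_set = {p.fps for p in paths.values()}
    if len(fps_set) != 1:
        raise ValueError("all paths must share one fps")
    fps = fps_set.pop()
    n_blob = {a: p.n_frames for a, p in paths.items()}
    if len(set(n_blob.values())) != 1:
        raise ValueError("all paths must cover the same number of frames")
    n_move = next(iter(n_blob.values()))
    n_leader = int(round(scene.leader_s * fps))

    width, height = scene.frame_size
    tracks: dict[int, np.ndarray] = {}
    for arena_id, p in paths.items():
        if arena_id not in range(len(scene.arenas)):
            raise KeyError(f"arena {arena_id} not in scene")
        xy = make_scripted_track(p)
        if not _contains(scene.arenas[arena_id], xy).all():
            raise ValueError(f"path for arena {arena_id} leaves its arena")
        tracks[arena_id] = xy

    major, minor, blob_level = scene.blob
    base = np.full((height, width), scene.background_level, dtype=np.float64)
    n_total = n_leader + n_move
    frames = np.empty((n_total, height, width), dtype=np.uint8)
    rng = np.random.default_rng(scene.seed)
    for f in range(n_total):
        img = base.copy()
        if f >= n_leader:
            for arena_id, xy in tracks.items():
                cx, cy = xy[f - n_leader]
                rr, cc = _draw_ellipse(cy, cx, minor / 2.0, major / 2.0, shape=img.shape)
                img[rr, cc] = blob_level
        if scene.noise_sigma > 0:
            img = img + rng.normal(0.0, scene.noise_sigma, img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        first_frame=n_leader,
        positions=tracks,
        path_length_px={a: paths[a].length_px for a in paths},
        fps=fps,
    )
    if out_path is not None:
        write_video(out_path, frames, fps)
    return frames, truth


# ---------------------------------------------------------------------------
# populations with planted cluster structure

Archetype = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class PopulationSpec:
    """A population of series drawn from a few archetype curves plus noise."""

    cluster_archetypes: tuple
    n_per_cluster: int = 5
    length: int = 60
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.cluster_archetypes) < 2:
            raise ValueError("need at least 2 archetypes")
        if self.n_per_cluster < 1:
            raise ValueError("n_per_cluster must be >= 1")
        if self.length < 2:
            raise ValueError("length must be >= 2")


def trajectory_archetypes() -> dict[str, Archetype]:
    """Built-in 2-D path shapes on the unit square, parameterized on t in [0, 1].

    The four shapes (straight run, left-curving arc, right-curving arc,
    inward spiral) are caricatures of locomotion styles an open-field cohort
    can split into.
    """

    def line(t):
        return np.column_stack([0.1 + 0.8 * t, 0.1 + 0.8 * t])

    def arc_left(t):
        ang = math.pi * t
        return np.column_stack([0.5 + 0.35 * np.cos(ang), 0.5 - 0.35 * np.sin(ang)])

    def arc_right(t):
        ang = math.pi * t
        return np.column_stack([0.5 + 0.35 * np.cos(ang), 0.5 + 0.35 * np.sin(ang)])

    def spiral(t):
        ang = 4.0 * math.pi * t
        r = 0.40 * (1.0 - 0.85 * t)
        return np.column_stack([0.5 + r * np.cos(ang), 0.5 + r * np.sin(ang)])

    return {"line": line, "arc_left": arc_left, "arc_right": arc_right, "spiral": spiral}


def angle_archetypes() -> dict[str, Archetype]:
    """Built-in 1-D heading profiles (degrees) on t in [0, 1]: a straight
    runner (constant heading), a steady turner (linear ramp through a full
    revolution), and a scanner (sinusoidal sweep)."""

    def constant(t):
        return np.zeros_like(t)

    def ramp(t):
        return 360.0 * t

    def oscillation(t):
        return 90.0 * np.sin(6.0 * math.pi * t)

    return {"constant": constant, "ramp": ramp, "oscillation": oscillation}


def _resolve_archetype(spec_item, kind: str) -> Archetype:
    if callable(spec_item):
        return spec_item
    table = trajectory_archetypes() if kind == "trajectory2d" else angle_archetypes()
    try:
        return table[spec_item]
    except KeyError:
        raise ValueError(f"unknown {kind} archetype {spec_item!r}") from None


def simulate_population(
    spec: PopulationSpec, kind: str
) -> tuple[list[np.ndarray], np.ndarray]:
    """Draw a population of series with planted cluster labels.

    ``kind`` is ``"trajectory2d"`` (series are (length, 2) arrays) or
    ``"angle1d"`` (series are (length,) arrays).  Each series is its
    archetype evaluated at ``length`` uniformly spaced samples plus
    independent Gaussian noise; labels are returned in generation order.
    """
    if kind not in ("trajectory2d", "angle1d"):
        raise ValueError(f"unknown population kind {kind!r}")
    funcs = [_resolve_archetype(a, kind) for a in spec.cluster_archetypes]
    t = np.linspace(0.0, 1.0, spec.length)
    rng = np.random.default_rng(spec.seed)
    series: list[np.ndarray] = []
    labels: list[int] = []
    for label, f in enumerate(funcs):
        base = np.asarray(f(t), dtype=float)
        expected = (spec.length, 2) if kind == "trajectory2d" else (spec.length,)
        if base.shape != expected:
            raise ValueError(f"archetype {label} returned shape {base.shape}, expected {expected}")
        for _ in range(spec.n_per_cluster):
            noisy = base + rng.normal(0.0, spec.noise_sigma, base.shape) if spec.noise_sigma > 0 else base.copy()
            series.append(noisy)
            labels.append(label)
    return series, np.asarray(labels)
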