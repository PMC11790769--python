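"""Pixel-to-cm calibration, ROI bookkeeping, and the standard behavioral metrics.

For the open-field test the metrics are total distance traveled and, per
region of interest (ROI, e.g. center vs. periphery): distance, time, and
mean speed.  For the light-dark box they are time in the lighted compartment
and the number of compartment transitions.  Zone membership is decided by
the centroid; a step's distance is attributed to the zone of its *earlier*
frame, which makes the per-ROI distance decomposition exactly conservative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .tracking import Track

NONE_LABEL = "none"


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel-to-cm scale from two reference points of known separation."""

    point_a: tuple[float, float]
    point_b: tuple[float, float]
    real_length_cm: float

    @property
    def scale(self) -> float:
        """cm per pixel."""
        d = math.dist(self.point_a, self.point_b)
        return self.real_length_cm / d


def calibrate(point_a, point_b, real_length_cm: float) -> Calibration:
    if tuple(point_a) == tuple(point_b):
        raise ValueError("calibration points must be distinct")
    if real_length_cm <= 0:
        raise ValueError("real_length_cm must be positive")
    return Calibration(tuple(point_a), tuple(point_b), float(real_length_cm))


def _as_polygon(shape) -> Polygon:
    if isinstance(shape, Polygon):
        return shape
    shape = tuple(shape)
    if len(shape) == 4 and all(np.isscalar(v) for v in shape):
        x0, y0, x1, y1 = shape
        return box(x0, y0, x1, y1)
    return Polygon(shape)


@dataclass
class ArenaLayout:
    """Arenas and their named ROIs.

    ``rois[arena_id]`` is an ordered list of (name, polygon); declaration
    order is the tie-break when drawn ROIs overlap, and boundary points
    belong to the drawn ROI.  ``complement_roi`` optionally names the part
    of the arena not covered by any drawn ROI (e.g. "periphery" when only
    the center square is drawn).
    """

    arenas: dict[int, Polygon]
    rois: dict[int, list[tuple[str, Polygon]]] = field(default_factory=dict)
    complement_roi: str | None = None

    def __post_init__(self):
        self.arenas = {a: _as_polygon(p) for a, p in self.arenas.items()}
        self.rois = {
            a: [(name, _as_polygon(p)) for name, p in lst] for a, lst in self.rois.items()
        }

    def roi_names(self, arena_id: int) -> list[str]:
        names = [name for name, _ in self.rois.get(arena_id, [])]
        if self.complement_roi is not None:
            names.append(self.complement_roi)
        return names

    def label_point(self, arena_id: int, x: float, y: float) -> str:
        pt = Point(x, y)
        for name, poly in self.rois.get(arena_id, []):
            if poly.intersects(pt):  # boundary counts as inside the drawn ROI
                return name
        if self.complement_roi is not None and self.arenas[arena_id].intersects(pt):
            return self.complement_roi
        return NONE_LABEL


@dataclass
class BehaviorMetrics:
    """Per-track behavioral summary over the evaluation window."""

    total_distance_cm: float
    per_roi: pd.DataFrame  # columns: roi, time_s, distance_cm, mean_speed_cm_s, speed_defined
    transitions: int
    window: tuple[float, float]  # (start_s, end_s)


def total_distance(track: Track, cal: Calibration, max_step_px: float | None = None) -> float:
    """Total path length in cm over valid consecutive samples.

    Steps longer than ``max_step_px`` (tracking teleports) contribute zero
    and are logged as a warning.
    """
    steps = step_lengths_px(track, max_step_px)
    return float(np.nansum(steps)) * cal.scale


def step_lengths_px(track: Track, max_step_px: float | None = None) -> np.ndarray:
    """Per-step pixel displacements; NaN where either endpoint is invalid.

    Entry i is the displacement from sample i to i+1 (length n-1).
    """
    xy = track.samples
    d = np.hypot(*np.diff(xy, axis=0).T) if len(xy) > 1 else np.zeros(0)
    if max_step_px is not None:
        big = d > max_step_px
        if big.any():
            warnings.warn(f"{int(big.sum())} steps exceed {max_step_px} px; treated as 0", stacklevel=2)
        d = np.where(big, 0.0, d)
    return d


def roi_membership(track: Track, layout: ArenaLayout) -> list[str]:
    """Per-frame ROI label for the track's centroid positions.

    Frames with no position yet (before the first detection) are labeled
    "none"; a warning is emitted if any positioned frame falls outside every
    ROI and no complement is defined.
    """
    if track.arena_id not in layout.arenas:
        raise KeyError(f"arena {track.arena_id} not in layout")
    labels = []
    unmatched = 0
    for (x, y), ok in zip(track.samples, track.valid):
        if not ok:
            labels.append(NONE_LABEL)
            continue
        lab = layout.label_point(track.arena_id, x, y)
        if lab == NONE_LABEL:
            unmatched += 1
        labels.append(lab)
    if unmatched:
        warnings.warn(
            f"{unmatched} frames outside all ROIs (no complement defined); labeled 'none'",
            stacklevel=2,
        )
    return labels


def count_transitions(membership: list[str], debounce_frames: int = 1) -> int:
    """Count zone changes where the new zone persists >= debounce_frames.

    A short excursion that returns before being confirmed leaves the current
    zone unchanged and counts nothing.
    """
    if len(membership) == 0:
        raise ValueError("empty membership series")
    if debounce_frames < 1:
        raise ValueError("debounce_frames must be >= 1")
    current = membership[0]
    count = 0
    i = 1
    n = len(membership)
    while i < n:
        if membership[i] != current:
            j = i
            while j < n and membership[j] == membership[i]:
                j += 1
            if j - i >= debounce_frames:
                count += 1
                current = membership[i]
            i = j
        else:
            i += 1
    return count


def roi_metrics(
    track: Track,
    layout: ArenaLayout,
    cal: Calibration,
    max_step_px: float | None = None,
    debounce_frames: int = 1,
) -> BehaviorMetrics:
    """Compute the full per-ROI behavioral summary.

    time_s(ROI) = frames in ROI / fps; distance_cm(ROI) sums the steps whose
    earlier frame is in the ROI; mean speed = distance / time (reported as 0
    with ``speed_defined=False`` when the ROI was never visited).  The per-ROI
    times sum to the window duration and the per-ROI distances to the total
    distance, exactly.
    """
    if len(track) == 0:
        raise ValueError("zero-length window")
    membership = roi_membership(track, layout)
    steps_px = step_lengths_px(track, max_step_px)
    steps_cm = np.nan_to_num(steps_px) * cal.scale

    names = layout.roi_names(track.arena_id)
    if NONE_LABEL in membership and NONE_LABEL not in names:
        names = names + [NONE_LABEL]
    rows = []
    for name in names:
        in_roi = np.array([m == name for m in membership])
        t = float(in_roi.sum()) / track.fps
        d = float(steps_cm[in_roi[:-1]].sum()) if len(steps_cm) else 0.0
        defined = t > 0
        rows.append((name, t, d, d / t if defined else 0.0, defined))
    per_roi = pd.DataFrame(
        rows, columns=["roi", "time_s", "distance_cm", "mean_speed_cm_s", "speed_defined"]
    )
    window = (track.start_frame / track.fps, track.end_frame / track.fps)
    return BehaviorMetrics(
        total_distance_cm=float(steps_cm.sum()),
        per_roi=per_roi,
        transitions=count_transitions(membership, debounce_frames),
        window=window,
    )


def occupancy_heatmap(
    track: Track, arena_rect: tuple[float, float, float, float], bins: int | tuple[int, int] = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D occupancy histogram of the centroid over the arena.

    Returns (grid, x_edges, y_edges); grid[i, j] counts frames in x-bin i,
    y-bin j, and sums to the number of positioned frames.
    """
    if isinstance(bins, int):
        bins = (bins, bins)
    if min(bins) < 1:
        raise ValueError("bins must be >= 1 per axis")
    x0, y0, x1, y1 = arena_rect
    xy = track.samples[track.valid]
    grid, xe, ye = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=bins, range=[[x0, x1], [y0, y1]]
    )
    return grid, xe, ye
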