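"""Animal detection by background subtraction and per-arena centroid tracking.

The detector follows the classic pipeline: subtract an animal-free reference
frame, binarize the (signed) difference at an intensity threshold, clean the
mask morphologically, discard blobs below a minimum area, and take the
centroid of the largest surviving connected component.  One centroid track
is produced per arena; arenas are disjoint, so identity is by containment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import binary_closing, binary_opening, disk

from .videoio import read_video, to_gray

log = logging.getLogger(__name__)

Rect = tuple[float, float, float, float]


@dataclass(frozen=True)
class DetectionSettings:
    """Knobs of the background-subtraction detector.

    threshold
        minimum absolute intensity difference (0-255) for a pixel to count
        as animal.
    min_blob_area_px
        connected components smaller than this are discarded (droppings,
        reflections).
    polarity
        ``darker`` detects pixels darker than the background (dark animal on
        a light box), ``lighter`` the reverse, ``either`` uses |difference|.
    morphology_radius_px
        radius of the disk used for a binary opening followed by closing;
        0 disables morphology.
    fps_override
        frame rate to use when the container metadata has none (or to
        override it).
    """

    threshold: float = 50.0
    min_blob_area_px: int = 20
    polarity: str = "darker"
    morphology_radius_px: int = 0
    fps_override: float | None = None

    def __post_init__(self):
        if not 0 < self.threshold < 255:
            raise ValueError("threshold must be in (0, 255)")
        if self.min_blob_area_px < 1:
            raise ValueError("min_blob_area_px must be >= 1")
        if self.polarity not in ("darker", "lighter", "either"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.morphology_radius_px < 0:
            raise ValueError("morphology_radius_px must be >= 0")


@dataclass(frozen=True)
class BackgroundModel:
    """An animal-free grayscale reference frame."""

    image: np.ndarray
    source: str  # leader_frame | external_photo | median_stack | none


@dataclass
class Track:
    """Per-arena centroid track over an evaluation window.

    ``samples`` is a (n, 2) float array of (x, y) pixel positions covering
    frames ``start_frame .. end_frame - 1``; ``detected`` flags frames with a
    real detection (others carry the last detected position forward, or NaN
    before the first detection); ``interpolated`` flags gap-filled frames.
    """

    arena_id: int
    fps: float
    start_frame: int
    end_frame: int
    samples: np.ndarray
    detected: np.ndarray
    interpolated: np.ndarray = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.samples), dtype=bool)
        n = self.end_frame - self.start_frame
        if not (len(self.samples) == len(self.detected) == len(self.interpolated) == n):
            raise ValueError("sample arrays must cover [start_frame, end_frame)")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame)

    @property
    def times_s(self) -> np.ndarray:
        """Time of each sample relative to the start of the window."""
        return (self.frames - self.start_frame) / self.fps

    @property
    def is_empty(self) -> bool:
        return not self.detected.any()

    @property
    def valid(self) -> np.ndarray:
        """Frames with a usable position (detected, carried or interpolated)."""
        return ~np.isnan(self.samples[:, 0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_s": self.times_s,
                "arena": self.arena_id,
                "x_px": self.samples[:, 0],
                "y_px": self.samples[:, 1],
                "detected": self.detected.astype(int),
                "interpolated": self.interpolated.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fps: float | None = None) -> "Track":
        df = df.sort_values("frame").reset_index(drop=True)
        if fps is None:
            if "time_s" in df and len(df) > 1:
                fps = float((len(df) - 1) / (df["time_s"].iloc[-1] - df["time_s"].iloc[0]))
            else:
                raise ValueError("fps not provided and not recoverable from time_s")
        start = int(df["frame"].iloc[0])
        return cls(
            arena_id=int(df["arena"].iloc[0]) if "arena" in df else 0,
            fps=fps,
            start_frame=start,
            end_frame=start + len(df),
            samples=df[["x_px", "y_px"]].to_numpy(float),
            detected=df["detected"].to_numpy(bool) if "detected" in df else np.ones(len(df), bool),
            interpolated=df["interpolated"].to_numpy(bool) if "interpolated" in df else None,
        )


def estimate_background(
    frames: np.ndarray, frame_range: tuple[int, int], method: str = "leader_frame"
) -> BackgroundModel:
    """Build the reference frame from a range of (animal-free) frames.

    ``leader_frame`` takes the first frame of the half-open range;
    ``median_stack`` takes the per-pixel median over it, which also works if
    the animal is present but occupies each pixel less than half the time.
    """
    lo, hi = frame_range
    if not (0 <= lo < hi <= len(frames)):
        raise IndexError(f"frame range {frame_range} out of bounds for {len(frames)} frames")
    if method == "leader_frame":
        img = to_gray(frames[lo])
    elif method == "median_stack":
        stack = np.stack([to_gray(f) for f in frames[lo:hi]])
        img = np.median(stack, axis=0)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return BackgroundModel(image=img, source=method)


def _difference(frame: np.ndarray, bg: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "darker":
        return bg - frame
    if polarity == "lighter":
        return frame - bg
    return np.abs(frame - bg)


def detect_in_frame(
    frame: np.ndarray,
    bg: BackgroundModel,
    settings: DetectionSettings,
    arena: Rect,
) -> tuple[float, float] | None:
    """Detect the animal inside one arena; returns (x, y) or None.

    The centroid is the unweighted mean pixel position of the largest
    connected component at least ``min_blob_area_px`` big.
    """
    if bg.image is None:
        raise ValueError("detection requires a background model")
    gray = to_gray(frame)
    if gray.shape != bg.image.shape:
        raise ValueError("frame and background dimensions differ")
    x0, y0, x1, y1 = arena
    r0, r1 = max(0, int(np.floor(y0))), min(gray.shape[0], int(np.ceil(y1)) + 1)
    c0, c1 = max(0, int(np.floor(x0))), min(gray.shape[1], int(np.ceil(x1)) + 1)
    diff = _difference(gray[r0:r1, c0:c1], bg.image[r0:r1, c0:c1], settings.polarity)
    mask = diff > settings.threshold
    if settings.morphology_radius_px > 0:
        selem = disk(settings.morphology_radius_px)
        mask = binary_closing(binary_opening(mask, selem), selem)
    if not mask.any():
        return None
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= settings.min_blob_area_px)
    if keep.size == 0:
        return None
    best = keep[np.argmax(areas[keep])] + 1
    cy, cx = ndimage.center_of_mass(labels == best)
    return (cx + c0, cy + r0)


def track_video(
    video,
    arenas: dict[int, Rect],
    settings: DetectionSettings,
    background: BackgroundModel,
    start_frame: int,
    end_frame: int,
    fps: float | None = None,
) -> dict[int, Track]:
    """Track every arena over the half-open window [start_frame, end_frame).

    ``video`` is a frame stack or a path to a video file.  Frames without a
    detection carry the last detected position forward (NaN before the first
    detection); an arena with zero detections yields an empty-track flag and
    a warning rather than an error.
    """
    if isinstance(video, (str, Path)):
        frames, meta_fps = read_video(video)
        if fps is None:
            fps = meta_fps
    else:
        frames = np.asarray(video)
    if settings.fps_override is not None:
        fps = settings.fps_override
    if fps is None:
        raise ValueError("fps unavailable: not in container metadata and no fps_override set")
    if not 0 <= start_frame < end_frame <= len(frames):
        raise IndexError(f"window [{start_frame}, {end_frame}) out of bounds")
    if not 1 <= len(arenas) <= 4:
        raise ValueError("1..4 arenas supported")

    n = end_frame - start_frame
    out: dict[int, Track] = {}
    for arena_id, rect in arenas.items():
        xy = np.full((n, 2), np.nan)
        det = np.zeros(n, dtype=bool)
        for i, f in enumerate(range(start_frame, end_frame)):
            c = detect_in_frame(frames[f], background, settings, rect)
            if c is not None:
                xy[i] = c
                det[i] = True
            elif i > 0:
                xy[i] = xy[i - 1]
        if not det.any():
            warnings.warn(f"arena {arena_id}: no detections in window", stacklevel=2)
            log.warning("arena %s: no detections in [%d, %d)", arena_id, start_frame, end_frame)
        out[arena_id] = Track(
            arena_id=arena_id,
            fps=float(fps),
            start_frame=start_frame,
            end_frame=end_frame,
            samples=xy,
            detected=det,
        )
    return out


def fill_gaps(track: Track, max_gap_frames: int) -> Track:
    """Linearly interpolate runs of <= max_gap_frames missed detections.

    Only gaps flanked by detections on both sides are filled; longer gaps
    keep the carry-forward positions.  Interpolated frames are flagged.
    """
    det = track.detected
    xy = track.samples.copy()
    interp = track.interpolated.copy()
    idx = np.flatnonzero(det)
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap_frames:
            w = np.arange(1, gap + 1) / (gap + 1)
            xy[a + 1 : b] = xy[a] * (1 - w[:, None]) + xy[b] * w[:, None]
            interp[a + 1 : b] = True
    return Track(
        arena_id=track.arena_id,
        fps=track.fps,
        start_frame=track.start_frame,
        end_frame=track.end_frame,
        samples=xy,
        detected=det.copy(),
        interpolated=interp,
    )
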