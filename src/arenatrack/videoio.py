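"""Reading and writing behavior videos.

The default container is multi-page grayscale TIFF: it is lossless, carries
the frame rate in its metadata, and round-trips bit-exactly, which matters
for seeded synthetic fixtures.  Other containers (PNG stacks, anything an
installed imageio plugin can decode) are read through imageio as a fallback;
those readers may not expose a frame rate, in which case the caller must
supply one (``DetectionSettings.fps_override``).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import tifffile

#: luma weights for RGB -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

_TIFF_SUFFIXES = {".tif", ".tiff"}


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to 2-D float64 grayscale (luma weighting for RGB)."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3] @ _LUMA
    return frame.astype(np.float64)


def write_video(path: str | os.PathLike, frames: np.ndarray, fps: float) -> None:
    """Write a (n_frames, height, width) uint8 stack as a multi-page TIFF.

    Raises ``ValueError`` for containers that need an unavailable encoder.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"expected (frames, height, width) stack, got shape {frames.shape}")
    if path.suffix.lower() not in _TIFF_SUFFIXES:
        raise ValueError(
            f"cannot encode container {path.suffix!r}; use .tif (lossless multi-page TIFF)"
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frames.astype(np.uint8), metadata={"fps": float(fps)})


def read_video(path: str | os.PathLike) -> tuple[np.ndarray, float | None]:
    """Read a video as a (n_frames, height, width[, 3]) array plus fps if known."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            fps = None
            meta = tf.shaped_metadata
            if meta and "fps" in meta[0]:
                fps = float(meta[0]["fps"])
        if frames.ndim == 2:
            frames = frames[None]
        return frames, fps
    import imageio.v3 as iio

    frames = iio.imread(path, index=None)
    if frames.ndim == 2:
        frames = frames[None]
    fps = None
    try:
        meta = iio.immeta(path)
        if "fps" in meta:
            fps = float(meta["fps"])
    except Exception:
        pass
    return frames, fps
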