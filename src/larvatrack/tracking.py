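"""Larval detection in time-lapse frames.

Pipeline: average-intensity background model → absolute background
subtraction → binarization (Otsu or fixed threshold) → 8-connected particle
detection with binary (unweighted) centroids.  Each stage is exposed
separately; :func:`track_stack` chains them over a frame stack.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

logger = logging.getLogger(__name__)


@dataclass
class FrameStack:
    """Ordered equal-sized greyscale frames at a fixed nominal interval."""

    frames: list[np.ndarray]
    frame_interval_s: float = 3.0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.ndim != 2 or f.shape != shape:
                raise ValueError("all frames must be 2-D and equally sized")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def save_png_dir(self, directory: str | Path) -> None:
        """Write frames as zero-padded numbered 8-bit PNG files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        width = max(5, len(str(len(self.frames) - 1)))
        for i, f in enumerate(self.frames):
            iio.imwrite(directory / f"frame_{i:0{width}d}.png", f.astype(np.uint8))

    def save_tiff(self, path: str | Path) -> None:
        """Write the stack as a single multi-page 8-bit TIFF."""
        tifffile.imwrite(path, np.stack(self.frames).astype(np.uint8))


def load_frames(path: str | Path, frame_interval_s: float = 3.0) -> FrameStack:
    """Load a PNG/TIFF frame directory or a multi-page TIFF into a stack.

    RGB frames are converted to greyscale on load; files in a directory are
    taken in sorted name order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = [to_greyscale(iio.imread(p)) for p in files]
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        frames = [to_greyscale(a) for a in arr]
    return FrameStack(frames=frames, frame_interval_s=frame_interval_s)


@dataclass
class BackgroundModel:
    """Per-pixel arithmetic mean intensity over all frames of a stack."""

    image: np.ndarray


@dataclass(frozen=True)
class Detection:
    frame_index: int
    centroid: tuple[float, float]  # (x, y) pixels
    area_px: int


def to_greyscale(frame: np.ndarray) -> np.ndarray:
    """Greyscale conversion: unweighted channel mean, rounded half-up.

    Single-channel input passes through unchanged.
    """
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        mean = frame.astype(np.float64).mean(axis=2)
        return np.floor(mean + 0.5).astype(frame.dtype)
    raise ValueError(f"expected 1 or 3 channels, got shape {frame.shape}")


def build_background(stack: FrameStack) -> BackgroundModel:
    """Average-intensity background: per-pixel mean over every frame."""
    acc = np.zeros(stack.frames[0].shape, dtype=np.float64)
    for f in stack.frames:
        acc += f
    return BackgroundModel(image=acc / len(stack.frames))


def subtract_and_binarize(
    frame: np.ndarray,
    bg: BackgroundModel,
    method: str = "otsu",
    min_fg_level: float = 10.0,
) -> np.ndarray:
    """Binarize the absolute difference between a frame and the background.

    ``method`` is ``"otsu"`` or ``"fixed:K"`` (threshold K grey levels).
    With Otsu, a threshold below ``min_fg_level`` indicates an all-background
    frame (Otsu always splits something) and the mask is declared empty.
    """
    if frame.shape != bg.image.shape:
        raise ValueError("frame and background dimensions differ")
    diff = np.abs(frame.astype(np.float64) - bg.image)
    if method == "otsu":
        if float(diff.max()) <= float(diff.min()):
            return np.zeros(frame.shape, dtype=bool)
        thr = threshold_otsu(diff)
        if thr < min_fg_level:
            return np.zeros(frame.shape, dtype=bool)
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return diff > thr


def detect_particles(mask: np.ndarray, min_area: int = 10) -> list[Detection]:
    """8-connected particles of ``mask`` with at least ``min_area`` pixels.

    Centroid is the unweighted mean of member-pixel coordinates (pixel
    centres at integers), reported as (x, y) = (column, row).  Output is
    sorted by area descending, ties broken by the component bounding box's
    top-left pixel (row, then column).
    """
    lab = label(mask, connectivity=2)
    dets: list[tuple[int, int, int, Detection]] = []
    for rp in regionprops(lab):
        if rp.area < min_area:
            continue
        cy, cx = rp.centroid
        dets.append(
            (
                -int(rp.area),
                rp.bbox[0],
                rp.bbox[1],
                Detection(frame_index=-1, centroid=(float(cx), float(cy)), area_px=int(rp.area)),
            )
        )
    dets.sort(key=lambda t: t[:3])
    return [d for *_, d in dets]


def track_stack(
    stack: FrameStack,
    method: str = "otsu",
    min_area: int = 10,
    min_fg_level: float = 10.0,
) -> pd.DataFrame:
    """Run the full detection pipeline over a stack.

    Returns a table ``frame,x,y,area,n_detections_in_frame`` with zero or
    more rows per frame (frames with no detection contribute no rows);
    multi-detection resolution is left to the trajectory module.
    """
    bg = build_background(stack)
    rows = []
    for i, frame in enumerate(stack.frames):
        mask = subtract_and_binarize(frame, bg, method=method, min_fg_level=min_fg_level)
        dets = detect_particles(mask, min_area=min_area)
        for d in dets:
            rows.append(
                {
                    "frame": i,
                    "x": d.centroid[0],
                    "y": d.centroid[1],
                    "area": d.area_px,
                    "n_detections_in_frame": len(dets),
                }
            )
        logger.debug("frame %d: %d detection(s)", i, len(dets))
    return pd.DataFrame(rows, columns=["frame", "x", "y", "area", "n_detections_in_frame"])
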