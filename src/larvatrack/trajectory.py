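"""Trajectory quality control: one position per frame, plus step distances.

Cleaning rules applied to raw per-frame detections:

1. detections outside the dish (beyond a small tolerance) are removed;
2. frames with several detections take the unweighted mean of the centroids;
3. frames with no detection carry the immediately previous position forward
   (frames before the first detection are back-filled from it);
4. larvae with too many non-detected frames are flagged for exclusion.

Per-frame provenance is recorded so downstream analyses can audit the fill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import ArenaSpec

logger = logging.getLogger(__name__)

#: dish-membership tolerance, px (centroid jitter at the wall)
DEFAULT_TOLERANCE_PX = 2.0

#: fraction of non-detected frames above which a larva is flagged for exclusion
DEFAULT_EXCLUSION_MISSING_FRAC = 0.20


@dataclass
class CleanTrajectory:
    """Exactly one (x, y) position per frame with fill provenance.

    ``provenance`` values: ``detected``, ``averaged`` (multi-detection mean),
    ``carried_forward`` (gap filled from the previous frame), or
    ``back_filled`` (leading gap filled from the first detection).
    """

    positions: np.ndarray
    provenance: np.ndarray
    frame_interval_s: float = 3.0

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def missing_fraction(self) -> float:
        """Fraction of frames whose position was filled rather than detected."""
        filled = np.isin(self.provenance, ("carried_forward", "back_filled"))
        return float(filled.mean())

    def flagged_for_exclusion(
        self, max_missing_frac: float = DEFAULT_EXCLUSION_MISSING_FRAC
    ) -> bool:
        """True when too few frames had a real detection to trust the record."""
        return self.missing_fraction > max_missing_frac

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "provenance": self.provenance,
            }
        )


def filter_out_of_arena(
    detections: pd.DataFrame,
    arena: ArenaSpec,
    tolerance_px: float = DEFAULT_TOLERANCE_PX,
) -> pd.DataFrame:
    """Drop detections farther than ``dish_radius + tolerance`` from the dish centre."""
    cx, cy = arena.dish_center
    dist = np.hypot(detections["x"] - cx, detections["y"] - cy)
    keep = dist <= arena.dish_radius_px + tolerance_px
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("removed %d out-of-dish detection(s)", n_dropped)
    return detections.loc[keep].reset_index(drop=True)


def consolidate(detections: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple detections per frame to their coordinate average.

    Frames with one detection pass through; frames with none emit no row.
    Returns ``frame,x,y,provenance`` with provenance ``detected``/``averaged``.
    """
    if detections.empty:
        return pd.DataFrame(columns=["frame", "x", "y", "provenance"])
    grouped = detections.groupby("frame", sort=True)
    agg = grouped.agg(x=("x", "mean"), y=("y", "mean"), n=("x", "size")).reset_index()
    agg["provenance"] = np.where(agg["n"] > 1, "averaged", "detected")
    return agg[["frame", "x", "y", "provenance"]]


def fill_missing(
    points: pd.DataFrame,
    n_frames: int,
    frame_interval_s: float = 3.0,
) -> CleanTrajectory:
    """Fill non-detected frames to yield exactly one position per frame.

    Missing frames take the most recent earlier position (carry-forward);
    frames before the first detection take the first available position
    (back-fill).  Raises if no frame has a point at all.
    """
    if points.empty:
        raise ValueError("cannot build a trajectory: no detections in any frame")
    if n_frames < int(points["frame"].max()) + 1:
        raise ValueError("n_frames smaller than the largest detected frame index")
    pos = np.full((n_frames, 2), np.nan)
    prov = np.full(n_frames, "carried_forward", dtype=object)
    idx = points["frame"].to_numpy(dtype=int)
    pos[idx, 0] = points["x"].to_numpy(dtype=float)
    pos[idx, 1] = points["y"].to_numpy(dtype=float)
    prov[idx] = points["provenance"].to_numpy() if "provenance" in points else "detected"

    first = int(idx.min())
    if first > 0:
        pos[:first] = pos[first]
        prov[:first] = "back_filled"
    for i in range(first + 1, n_frames):
        if np.isnan(pos[i, 0]):
            pos[i] = pos[i - 1]
    return CleanTrajectory(
        positions=pos, provenance=prov, frame_interval_s=frame_interval_s
    )


def step_distances(traj: CleanTrajectory) -> np.ndarray:
    """Euclidean displacement per inter-frame interval (length ``n_frames - 1``)."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to compute step distances")
    d = np.diff(traj.positions, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def clean_detections(
    detections: pd.DataFrame,
    arena: ArenaSpec,
    n_frames: int | None = None,
    tolerance_px: float = DEFAULT_TOLERANCE_PX,
) -> CleanTrajectory:
    """Full QC chain: out-of-dish filter → consolidate → fill_missing."""
    kept = filter_out_of_arena(detections, arena, tolerance_px=tolerance_px)
    points = consolidate(kept)
    if n_frames is None:
        if points.empty:
            raise ValueError("cannot build a trajectory: no detections in any frame")
        n_frames = int(points["frame"].max()) + 1
    return fill_missing(points, n_frames, frame_interval_s=arena.frame_interval_s)
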