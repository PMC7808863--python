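"""Spatial occupancy analysis: time segments and dish-relative position use.

A 24-h record is split into eight contiguous 3-h segments and each segment's
position cloud is summarised by where the larva sat relative to the dish:
the median radial fraction (0 = centre, 1 = wall), the fraction of frames
near the diet blob, and the fraction in the outer dish annulus
(edge-following / thigmotaxis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .trajectory import CleanTrajectory

#: radial fraction above which a position counts as "at the edge"
DEFAULT_EDGE_CUTOFF = 0.8

#: margin added to the food radius for the "near food" test, px
DEFAULT_FOOD_MARGIN_PX = 10.0

DEFAULT_N_SEGMENTS = 8


@dataclass
class TimeSegment:
    """Contiguous frame range of a record with its position subset."""

    segment_index: int
    frame_start: int
    frame_end: int  # half-open
    positions: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frame_end - self.frame_start


@dataclass
class OccupancySummary:
    median_radial_fraction: float
    food_fraction: float
    edge_fraction: float


def segment_time(
    traj: CleanTrajectory, n_segments: int = DEFAULT_N_SEGMENTS
) -> list[TimeSegment]:
    """Split the frame axis into ``n_segments`` equal contiguous parts.

    Segment length is ``n_frames // n_segments``; any remainder goes to the
    last segment, so the segments partition the record exactly.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    n = traj.n_frames
    if n_segments > n:
        raise ValueError("more segments than frames")
    seg_len = n // n_segments
    segments = []
    for s in range(n_segments):
        start = s * seg_len
        end = (s + 1) * seg_len if s < n_segments - 1 else n
        segments.append(
            TimeSegment(
                segment_index=s,
                frame_start=start,
                frame_end=end,
                positions=traj.positions[start:end],
            )
        )
    return segments


def occupancy(
    seg: TimeSegment,
    arena: ArenaSpec,
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
    food_margin_px: float = DEFAULT_FOOD_MARGIN_PX,
) -> OccupancySummary:
    """Dish-relative occupancy summary of one segment's positions."""
    if len(seg.positions) == 0:
        raise ValueError("empty segment")
    cx, cy = arena.dish_center
    radial = np.hypot(seg.positions[:, 0] - cx, seg.positions[:, 1] - cy)
    frac = radial / arena.dish_radius_px
    fx, fy = arena.food_center
    food_dist = np.hypot(seg.positions[:, 0] - fx, seg.positions[:, 1] - fy)
    return OccupancySummary(
        median_radial_fraction=float(np.median(frac)),
        food_fraction=float((food_dist <= arena.food_radius_px + food_margin_px).mean()),
        edge_fraction=float((frac > edge_cutoff).mean()),
    )


def occupancy_table(
    traj: CleanTrajectory,
    arena: ArenaSpec,
    n_segments: int = DEFAULT_N_SEGMENTS,
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
    food_margin_px: float = DEFAULT_FOOD_MARGIN_PX,
) -> pd.DataFrame:
    """Per-segment occupancy summaries as one table."""
    rows = []
    for seg in segment_time(traj, n_segments):
        occ = occupancy(seg, arena, edge_cutoff=edge_cutoff, food_margin_px=food_margin_px)
        rows.append(
            {
                "segment": seg.segment_index,
                "frame_start": seg.frame_start,
                "frame_end": seg.frame_end,
                "n_frames": seg.n_frames,
                "median_radial_fraction": occ.median_radial_fraction,
                "food_fraction": occ.food_fraction,
                "edge_fraction": occ.edge_fraction,
            }
        )
    return pd.DataFrame(rows)


def export_distribution_plot(
    traj: CleanTrajectory,
    arena: ArenaSpec,
    out_dir: str | Path,
    n_segments: int = DEFAULT_N_SEGMENTS,
    label: str = "larva",
    color: str = "tab:blue",
) -> tuple[Path, Path]:
    """Scatter the per-frame positions, one panel per time segment.

    Writes ``<label>_segments.png`` and a verification CSV
    ``<label>_points.csv`` (columns ``segment,frame,x,y``; one row per
    frame) to ``out_dir``; returns both paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    segments = segment_time(traj, n_segments)

    ncols = min(4, n_segments)
    nrows = -(-n_segments // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False
    )
    rows = []
    for seg, ax in zip(segments, axes.flat):
        ax.add_patch(
            plt.Circle(arena.dish_center, arena.dish_radius_px, fill=False, color="grey")
        )
        if arena.food_radius_px > 0:
            ax.add_patch(
                plt.Circle(
                    arena.food_center, arena.food_radius_px, fill=False,
                    color="olive", linestyle=":",
                )
            )
        ax.scatter(seg.positions[:, 0], seg.positions[:, 1], s=1, color=color)
        ax.set_xlim(0, arena.width_px)
        ax.set_ylim(arena.height_px, 0)  # image convention: y down
        ax.set_aspect("equal")
        ax.set_title(f"segment {seg.segment_index}")
        for i in range(seg.n_frames):
            rows.append(
                {
                    "segment": seg.segment_index,
                    "frame": seg.frame_start + i,
                    "x": seg.positions[i, 0],
                    "y": seg.positions[i, 1],
                }
            )
    for ax in axes.flat[len(segments):]:
        ax.set_visible(False)
    fig.suptitle(label)
    fig.tight_layout()
    png_path = out_dir / f"{label}_segments.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    csv_path = out_dir / f"{label}_points.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return png_path, csv_path
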