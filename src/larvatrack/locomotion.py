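"""Behavioural quantification of a clean trajectory.

A per-interval displacement above 0.5 px scores the interval as movement;
the mean displacement of consecutive 30-s windows (10 intervals at 3 s)
above the same threshold marks the window as moving; maximal runs of moving
windows are single continuous-locomotion events (bouts).  Four per-larva
metrics summarise a record: total travel distance, median moving speed
(px per interval), median bout duration (in 30-s windows) and bout count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: movement threshold: per-interval displacement strictly above this is movement
DEFAULT_THRESHOLD_PX = 0.5

#: window length in intervals: 30 s at the nominal 3-s frame interval
DEFAULT_WINDOW_LEN = 10


def score_movement(
    steps: np.ndarray, threshold_px: float = DEFAULT_THRESHOLD_PX
) -> np.ndarray:
    """Boolean movement flag per interval: ``distance > threshold`` (strict).

    A displacement of exactly ``threshold_px`` counts as stationary.
    """
    steps = np.asarray(steps, dtype=float)
    if steps.size == 0:
        raise ValueError("empty step series")
    if threshold_px <= 0:
        raise ValueError("threshold_px must be positive")
    return steps > threshold_px


def window_means(
    steps: np.ndarray, window_len: int = DEFAULT_WINDOW_LEN
) -> tuple[np.ndarray, np.ndarray]:
    """Mean step distance of consecutive non-overlapping windows.

    Windows are anchored at interval 0; a trailing partial window is included
    and averaged over its actual members.  Returns ``(means, is_partial)``.
    """
    steps = np.asarray(steps, dtype=float)
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if steps.size == 0:
        raise ValueError("empty step series")
    n_full, rem = divmod(steps.size, window_len)
    means = []
    for w in range(n_full):
        means.append(steps[w * window_len : (w + 1) * window_len].mean())
    partial = np.zeros(n_full + (1 if rem else 0), dtype=bool)
    if rem:
        means.append(steps[n_full * window_len :].mean())
        partial[-1] = True
    return np.asarray(means), partial


def segment_bouts(
    window_means_px: np.ndarray, threshold_px: float = DEFAULT_THRESHOLD_PX
) -> pd.DataFrame:
    """Maximal runs of moving windows (mean > threshold, strict).

    Returns a table ``start_window,n_windows``, one row per continuous
    locomotion event, in temporal order; empty when nothing qualifies.
    """
    qual = np.asarray(window_means_px, dtype=float) > threshold_px
    starts, lengths = [], []
    i = 0
    n = qual.size
    while i < n:
        if qual[i]:
            j = i
            while j < n and qual[j]:
                j += 1
            starts.append(i)
            lengths.append(j - i)
            i = j
        else:
            i += 1
    return pd.DataFrame({"start_window": starts, "n_windows": lengths}, dtype=int)


@dataclass
class MetricsRecord:
    """Per-larva locomotion summary (the four standard metrics)."""

    larva_id: str
    group: str
    experiment_id: str
    total_distance_px: float
    median_speed_px_per_interval: float  # NaN when no interval moves
    median_bout_duration_windows: float  # NaN when there are no bouts
    bout_count: int

    def to_dict(self) -> dict:
        return {
            "larva_id": self.larva_id,
            "group": self.group,
            "experiment": self.experiment_id,
            "total_distance_px": self.total_distance_px,
            "median_speed_px_per_interval": self.median_speed_px_per_interval,
            "median_bout_duration_windows": self.median_bout_duration_windows,
            "bout_count": self.bout_count,
        }


def summarize(
    steps: np.ndarray,
    flags: np.ndarray,
    bouts: pd.DataFrame,
    larva_id: str = "larva",
    group: str = "",
    experiment_id: str = "",
) -> MetricsRecord:
    """Collapse one larva's record into a :class:`MetricsRecord`.

    Total distance is the sum of all step distances; median speed is taken
    over moving intervals only; median duration over bout lengths in
    windows.  Medians are NaN when their support is empty.
    """
    steps = np.asarray(steps, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if steps.shape != flags.shape:
        raise ValueError("steps and movement flags differ in length")
    moving = steps[flags]
    return MetricsRecord(
        larva_id=larva_id,
        group=group,
        experiment_id=experiment_id,
        total_distance_px=float(steps.sum()),
        median_speed_px_per_interval=float(np.median(moving)) if moving.size else math.nan,
        median_bout_duration_windows=(
            float(bouts["n_windows"].median()) if len(bouts) else math.nan
        ),
        bout_count=int(len(bouts)),
    )


def analyze_steps(
    steps: np.ndarray,
    threshold_px: float = DEFAULT_THRESHOLD_PX,
    window_len: int = DEFAULT_WINDOW_LEN,
    larva_id: str = "larva",
    group: str = "",
    experiment_id: str = "",
) -> tuple[MetricsRecord, pd.DataFrame]:
    """Full quantification chain for one step series: metrics + bout table."""
    flags = score_movement(steps, threshold_px)
    means, _ = window_means(steps, window_len)
    bouts = segment_bouts(means, threshold_px)
    rec = summarize(
        steps, flags, bouts, larva_id=larva_id, group=group, experiment_id=experiment_id
    )
    return rec, bouts


def metrics_table(records: list[MetricsRecord]) -> pd.DataFrame:
    """Stack per-larva records into the standard metrics table."""
    return pd.DataFrame([r.to_dict() for r in records])
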