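"""End-to-end conveniences tying the analysis stages together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .locomotion import (
    DEFAULT_THRESHOLD_PX,
    DEFAULT_WINDOW_LEN,
    analyze_steps,
    metrics_table,
)
from .synthetic import CohortMember, GroundTruth
from .trajectory import CleanTrajectory, step_distances


def truth_to_trajectory(truth: GroundTruth) -> CleanTrajectory:
    """Wrap simulated ground-truth positions as an already-clean trajectory."""
    return CleanTrajectory(
        positions=np.asarray(truth.positions, dtype=float),
        provenance=np.full(truth.n_frames, "detected", dtype=object),
        frame_interval_s=truth.frame_interval_s,
    )


def cohort_metrics(
    members: list[CohortMember],
    threshold_px: float = DEFAULT_THRESHOLD_PX,
    window_len: int = DEFAULT_WINDOW_LEN,
) -> pd.DataFrame:
    """Quantify every larva of a simulated cohort into one metrics table."""
    records = []
    for m in members:
        steps = step_distances(truth_to_trajectory(m.truth))
        rec, _ = analyze_steps(
            steps,
            threshold_px=threshold_px,
            window_len=window_len,
            larva_id=m.larva_id,
            group=m.group,
            experiment_id=m.experiment_id,
        )
        records.append(rec)
    return metrics_table(records)
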