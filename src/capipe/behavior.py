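"""Object-exploration scoring and the item-place discrimination index.

A trajectory sample counts as exploring an object when the tracked point lies
within the object radius (~2 cm by default) of the object's position; dwell
time is accumulated per sample and expressed as a percentage of total tracked
session time.  Optionally, immobile samples (speed below a threshold) can be
excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ArenaConfig, Trajectory, ValidationError, compute_speed


@dataclass
class ExplorationSummary:
    session_label: str
    exploration_time_s: dict[int, float]  # per object index
    total_session_time_s: float
    percent_of_total: dict[int, float]


def _sample_dwell(t: np.ndarray) -> np.ndarray:
    """Dwell time credited to each sample: half-interval to each neighbour."""
    dt = np.diff(t)
    dwell = np.empty(len(t))
    dwell[0] = dt[0] / 2
    dwell[-1] = dt[-1] / 2
    dwell[1:-1] = (dt[:-1] + dt[1:]) / 2
    return dwell


def score_object_exploration(
    trajectory: Trajectory,
    arena: ArenaConfig,
    session_label: str = "S1",
    exclude_immobility_below_cm_s: float | None = None,
) -> ExplorationSummary:
    """Per-object exploration time and percentage of total tracked time.

    With ``exclude_immobility_below_cm_s`` set, samples slower than the
    threshold are removed from both numerator and denominator.
    """
    if len(trajectory) < 2:
        raise ValidationError("trajectory too short to score")
    dwell = _sample_dwell(trajectory.t)
    keep = np.ones(len(trajectory), dtype=bool)
    if exclude_immobility_below_cm_s is not None:
        traj = trajectory if trajectory.speed is not None else compute_speed(trajectory)
        keep = traj.speed >= exclude_immobility_below_cm_s
    total = float(dwell[keep].sum())
    times: dict[int, float] = {}
    percents: dict[int, float] = {}
    for k, (ox, oy) in enumerate(arena.object_positions):
        near = np.hypot(trajectory.x - ox, trajectory.y - oy) <= arena.object_radius_cm
        t_k = float(dwell[near & keep].sum())
        times[k] = t_k
        percents[k] = 100.0 * t_k / total if total > 0 else 0.0
    return ExplorationSummary(session_label, times, total, percents)


def discrimination_index(t_displaced: float, t_stationary: float) -> float:
    """(displaced - stationary) / (displaced + stationary), in [-1, 1]."""
    if t_displaced < 0 or t_stationary < 0:
        raise ValidationError("exploration times must be non-negative")
    total = t_displaced + t_stationary
    if total == 0:
        raise ValidationError("discrimination index undefined: no object exploration")
    return (t_displaced - t_stationary) / total


def exploration_table(
    summaries: dict[str, ExplorationSummary],
    animal_id: str,
    displaced_object: int = 1,
) -> pd.DataFrame:
    """Tidy per-object exploration rows; DI filled for S3 rows only."""
    rows = []
    for label, summary in summaries.items():
        di = np.nan
        if label == "S3" and len(summary.exploration_time_s) >= 2:
            t_disp = summary.exploration_time_s[displaced_object]
            t_stat = sum(
                v for k, v in summary.exploration_time_s.items() if k != displaced_object
            )
            if t_disp + t_stat > 0:
                di = discrimination_index(t_disp, t_stat)
        for obj, t in summary.exploration_time_s.items():
            rows.append(
                {
                    "animal_id": animal_id,
                    "session": label,
                    "object_id": obj,
                    "exploration_time_s": t,
                    "percent": summary.percent_of_total[obj],
                    "DI": di if label == "S3" else np.nan,
                }
            )
    return pd.DataFrame(rows)
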