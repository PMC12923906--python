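"""Synchronous population bursts and their relationship to locomotion.

A burst is a maximal run of frames in which the z-scored mean population
dF/F exceeds z = 2; runs shorter than 50 ms are discarded as transient
fluctuations.  Burst magnitude is the mean z over the run (peak z is also
kept), and participation is the fraction of neurons with at least one
deconvolved event inside the burst window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BurstConfig, EventTrain, TraceMatrix, ValidationError


@dataclass
class BurstEvent:
    onset_s: float
    offset_s: float
    peak_time_s: float
    magnitude: float  # mean z over the run
    peak_z: float
    participation_frac: float | None = None

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def population_zscore(traces: TraceMatrix) -> np.ndarray:
    """Z-score each cell's trace, average across cells, z-score the average.

    Cells with zero variance carry no signal and are dropped with a warning.
    The output has mean 0 and unit (population) standard deviation.
    """
    values = traces.values
    if values.shape[0] == 0:
        raise ValidationError("empty trace matrix")
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance trace(s)")
    if not keep.any():
        raise ValidationError("all traces have zero variance")
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    pop = z.mean(axis=0)
    pop_sd = pop.std()
    if pop_sd == 0:
        raise ValidationError("population mean activity is constant")
    return (pop - pop.mean()) / pop_sd


def detect_bursts(
    popz: np.ndarray, fps: float, config: BurstConfig | None = None
) -> list[BurstEvent]:
    """Maximal supra-threshold runs of the population z-signal.

    Run membership uses strict ``z > threshold``; onsets/offsets are placed at
    the first frame above and first frame back below threshold respectively,
    so duration is the run length in frames over fps.
    """
    config = config or BurstConfig()
    popz = np.asarray(popz, dtype=float)
    if np.any(~np.isfinite(popz)):
        raise ValidationError("population signal contains non-finite values")
    above = popz > config.z_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(popz)]
    bursts = []
    for s, e in zip(starts, ends):
        duration = (e - s) / fps
        if duration < config.min_duration_s:
            continue
        run = popz[s:e]
        peak = int(np.argmax(run))
        bursts.append(
            BurstEvent(
                onset_s=s / fps,
                offset_s=e / fps,
                peak_time_s=(s + peak) / fps,
                magnitude=float(run.mean()),
                peak_z=float(run.max()),
            )
        )
    return bursts


def burst_session_metrics(bursts: Sequence[BurstEvent]) -> dict:
    """Session aggregates: count, mean duration, mean magnitude."""
    if not bursts:
        return {"count": 0, "mean_duration_s": np.nan, "mean_magnitude": np.nan}
    return {
        "count": len(bursts),
        "mean_duration_s": float(np.mean([b.duration_s for b in bursts])),
        "mean_magnitude": float(np.mean([b.magnitude for b in bursts])),
    }


def burst_participation(
    events: Mapping[str, EventTrain], bursts: Sequence[BurstEvent]
) -> tuple[list[float], float]:
    """Fraction of neurons with >= 1 event in each burst window, plus the mean.

    Fills each burst's ``participation_frac`` in place.
    """
    n_cells = len(events)
    if n_cells == 0:
        raise ValidationError("no event trains")
    fractions = []
    for burst in bursts:
        participants = sum(
            1
            for train in events.values()
            if np.any(
                (train.event_times >= burst.onset_s) & (train.event_times <= burst.offset_s)
            )
        )
        frac = participants / n_cells
        burst.participation_frac = frac
        fractions.append(frac)
    mean = float(np.mean(fractions)) if fractions else np.nan
    return fractions, mean


def activity_speed_correlation(
    popz: np.ndarray,
    speed: np.ndarray,
    fps: float,
    bursts: Sequence[BurstEvent] | None = None,
) -> dict:
    """Spearman correlation between population activity and running speed.

    ``speed`` must be sampled on the same frame base as ``popz``.  When bursts
    are supplied, the correlation restricted to burst frames is also returned.
    """
    popz = np.asarray(popz, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if len(popz) != len(speed):
        raise ValidationError("activity and speed must share the frame base")
    if np.all(popz == popz[0]) or np.all(speed == speed[0]):
        raise ValidationError("correlation undefined for constant input")
    rho, p = stats.spearmanr(popz, speed)
    out = {"rho": float(rho), "p": float(p)}
    if bursts is not None:
        mask = np.zeros(len(popz), dtype=bool)
        for b in bursts:
            mask[int(round(b.onset_s * fps)) : int(round(b.offset_s * fps))] = True
        if mask.sum() >= 3 and not np.all(speed[mask] == speed[mask][0]):
            rho_b, p_b = stats.spearmanr(popz[mask], speed[mask])
            out["rho_burst"], out["p_burst"] = float(rho_b), float(p_b)
        else:
            out["rho_burst"], out["p_burst"] = np.nan, np.nan
    return out


def burst_triggered_speed(
    speed: np.ndarray,
    bursts: Sequence[BurstEvent],
    fps: float,
    window_s: float = 5.0,
) -> dict:
    """Mean speed aligned to burst peaks, with a peak-vs-flank contrast.

    Bursts whose +/-window falls outside the session are skipped.  The
    contrast is the speed at the peak-centred bin minus the mean of the two
    flank bins at -window and +window.
    """
    speed = np.asarray(speed, dtype=float)
    half = int(round(window_s * fps))
    profiles = []
    for b in bursts:
        c = int(round(b.peak_time_s * fps))
        if c - half < 0 or c + half >= len(speed):
            continue
        profiles.append(speed[c - half : c + half + 1])
    if not profiles:
        raise ValidationError("no bursts with a full window inside the session")
    profile = np.mean(profiles, axis=0)
    contrast = float(profile[half] - (profile[0] + profile[-1]) / 2)
    lags = (np.arange(2 * half + 1) - half) / fps
    return {"lags_s": lags, "profile": profile, "contrast": contrast, "n_bursts": len(profiles)}


def burst_table(bursts: Sequence[BurstEvent], animal_id: str, session: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": animal_id,
                "session": session,
                "onset_s": b.onset_s,
                "offset_s": b.offset_s,
                "duration_s": b.duration_s,
                "magnitude": b.magnitude,
                "peak_z": b.peak_z,
                "participation_frac": b.participation_frac,
            }
            for b in bursts
        ],
        columns=[
            "animal_id", "session", "onset_s", "offset_s", "duration_s",
            "magnitude", "peak_z", "participation_frac",
        ],
    )
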