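"""Synthetic multi-session calcium-imaging datasets with planted ground truth.

The generator emulates the study design the pipeline analyses: four 10-minute
sessions (HA, S1, S2, S3) at 20 frames/s in a 40 x 40 cm arena with two
objects, hundreds of cells, planted place-tuned and object-tuned cells,
planted synchronous population bursts, controllable cross-session ensemble
overlap, and blocks of cells with correlated activity.

Events are drawn from an inhomogeneous Poisson process whose rate is the
product of a base rate, a Gaussian spatial gain (place cells), a burst gain
during planted bursts, and a shared log-OU modulation within correlated
blocks.  dF/F traces are the event train convolved with a
difference-of-exponentials calcium kernel plus white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    SESSION_LABELS,
    ArenaConfig,
    EventTrain,
    RecordingMeta,
    RegistrationMap,
    SessionDataset,
    TraceMatrix,
    Trajectory,
    ValidationError,
    write_session,
)

SESSION_PAIRS = (("HA", "S1"), ("S1", "S2"), ("S2", "S3"))


@dataclass(frozen=True)
class PlantedBurst:
    time_s: float
    duration_s: float
    participation_frac: float
    gain: float

    def __post_init__(self) -> None:
        if not (0 <= self.participation_frac <= 1):
            raise ValidationError("participation_frac must be in [0, 1]")
        if self.duration_s <= 0 or self.gain <= 0:
            raise ValidationError("burst duration and gain must be positive")


@dataclass
class GroundTruth:
    """Study-level planted structure: per-cell labels, bursts, overlap, blocks.

    ``cells`` is indexed by global cell id with columns ``place_cell``,
    ``tuning_x``, ``tuning_y``, ``tuning_width_cm``, ``peak_gain``,
    ``object_tuned``, ``base_rate_hz`` and ``block`` (-1 = no block).
    ``active`` is a boolean cells x sessions table of planned participation.
    """

    cells: pd.DataFrame
    active: pd.DataFrame
    bursts: dict[str, tuple[PlantedBurst, ...]]
    session_overlap: dict[tuple[str, str], float]
    block_log_sd: float = 0.5

    def __post_init__(self) -> None:
        for pair, frac in self.session_overlap.items():
            if not (0 <= frac <= 1):
                raise ValidationError(f"overlap {pair} = {frac} outside [0, 1]")

    def active_ids(self, session: str) -> pd.Index:
        return self.active.index[self.active[session]]


@dataclass(frozen=True)
class SimPreset:
    """Named parameter bundle fully determining a GroundTruth given a seed.

    ``vehicle_like`` mirrors a control-group profile: more bursts during the
    object sessions, strong S1->S2 reactivation that drops at the S3 object
    displacement, and object-tuned cells appearing in S3.  ``antagonist_like``
    mirrors a beta-adrenergic-blockade profile: fewer and weaker bursts,
    flatter reactivation, and reduced object tuning.
    """

    name: str
    frac_place_cells: float = 0.3
    frac_object_tuned: float = 0.1
    place_gain: float = 8.0
    object_gain: float = 8.0
    tuning_width_cm: float = 5.0
    base_rate_hz: float = 0.25
    base_rate_log_sd: float = 0.4
    burst_counts: Mapping[str, int] = field(
        default_factory=lambda: {"HA": 12, "S1": 20, "S2": 22, "S3": 20}
    )
    burst_gain: float = 8.0
    burst_duration_s: float = 0.4
    burst_participation: float = 0.8
    burst_min_separation_s: float = 12.0
    session_overlap: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("HA", "S1"): 0.6, ("S1", "S2"): 0.8, ("S2", "S3"): 0.4}
    )
    recruit_prob: float = 0.5
    p_active_ha: float = 0.9
    n_blocks: int = 2
    block_size: int = 8
    block_log_sd: float = 0.5
    noise_sigma: float = 0.15
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.6


def _antagonist_like() -> SimPreset:
    return SimPreset(
        name="antagonist_like",
        burst_counts={"HA": 12, "S1": 7, "S2": 7, "S3": 6},
        burst_gain=5.0,
        session_overlap={("HA", "S1"): 0.45, ("S1", "S2"): 0.5, ("S2", "S3"): 0.5},
        frac_object_tuned=0.03,
        object_gain=5.0,
    )


PRESETS: dict[str, SimPreset] = {
    "vehicle_like": SimPreset(name="vehicle_like"),
    "antagonist_like": _antagonist_like(),
}


def get_preset(name: str, **overrides) -> SimPreset:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    preset = PRESETS[name]
    return replace(preset, **overrides) if overrides else preset


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


def simulate_trajectory(
    arena: ArenaConfig,
    meta: RecordingMeta,
    mean_speed_cm_s: float = 8.0,
    tau_s: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Smooth open-field exploration: OU velocity reflected at the walls.

    Each velocity component follows an Ornstein-Uhlenbeck process with
    relaxation time ``tau_s`` and stationary speed scale set so the mean
    speed is roughly ``mean_speed_cm_s``; positions reflect off the arena
    boundary, keeping every sample in bounds.
    """
    if mean_speed_cm_s <= 0 or tau_s <= 0:
        raise ValidationError("mobility parameters must be positive")
    rng = np.random.default_rng(seed)
    n = meta.n_frames
    dt = 1.0 / meta.fps
    # stationary per-component sd: mean 2-D speed = sigma * sqrt(pi/2)
    sigma_v = mean_speed_cm_s / np.sqrt(np.pi / 2)
    a = np.exp(-dt / tau_s)
    b = sigma_v * np.sqrt(1 - a * a)
    vel = np.empty((n, 2))
    vel[0] = rng.normal(0, sigma_v, size=2)
    shocks = rng.normal(0, 1, size=(n - 1, 2))
    for i in range(1, n):
        vel[i] = a * vel[i - 1] + b * shocks[i - 1]
    pos = np.empty((n, 2))
    pos[0] = rng.uniform([0, 0], [arena.width_cm, arena.height_cm])
    steps = np.cumsum(vel[1:] * dt, axis=0)
    pos[1:] = pos[0] + steps
    # reflect into [0, L] via triangle-wave folding
    for k, L in enumerate((arena.width_cm, arena.height_cm)):
        p = np.mod(pos[:, k], 2 * L)
        pos[:, k] = np.where(p > L, 2 * L - p, p)
    t = np.arange(n) * dt
    return Trajectory(t, pos[:, 0], pos[:, 1])


# ---------------------------------------------------------------------------
# Single session
# ---------------------------------------------------------------------------


def calcium_kernel(fps: float, rise_s: float = 0.05, decay_s: float = 0.6) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalised to 1."""
    t = np.arange(0, 5 * decay_s, 1.0 / fps)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValidationError("degenerate kernel: rise must be faster than decay")
    return k / peak


def _cell_rate(
    row: pd.Series,
    x: np.ndarray,
    y: np.ndarray,
    arena: ArenaConfig,
) -> np.ndarray:
    """Per-frame firing rate (Hz) of one cell given the trajectory."""
    rate = np.full(x.shape, float(row["base_rate_hz"]))
    if row["place_cell"]:
        cx, cy = float(row["tuning_x"]), float(row["tuning_y"])
        if not (0 <= cx <= arena.width_cm and 0 <= cy <= arena.height_cm):
            raise ValidationError(f"tuning center ({cx}, {cy}) outside arena")
        w = float(row["tuning_width_cm"])
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        gain = 1.0 + (float(row["peak_gain"]) - 1.0) * np.exp(-d2 / (2 * w * w))
        rate = rate * gain
    return rate


def simulate_session(
    truth: GroundTruth,
    session_label: str,
    trajectory: Trajectory,
    meta: RecordingMeta,
    seed: int | np.random.SeedSequence = 0,
    noise_sigma: float = 0.15,
    kernel_rise_s: float = 0.05,
    kernel_decay_s: float = 0.6,
) -> SessionDataset:
    """Simulate one session for the cells active in ``session_label``.

    Per-session cell indices run 0..n_active-1 in global-id order; cell ids in
    the returned dataset are the string form of those indices.
    """
    arena = ArenaConfig(object_positions=((10.0, 20.0), (30.0, 20.0)))
    return simulate_session_in_arena(
        truth, session_label, trajectory, meta, arena, seed,
        noise_sigma=noise_sigma, kernel_rise_s=kernel_rise_s, kernel_decay_s=kernel_decay_s,
    )


def simulate_session_in_arena(
    truth: GroundTruth,
    session_label: str,
    trajectory: Trajectory,
    meta: RecordingMeta,
    arena: ArenaConfig,
    seed: int | np.random.SeedSequence = 0,
    noise_sigma: float = 0.15,
    kernel_rise_s: float = 0.05,
    kernel_decay_s: float = 0.6,
) -> SessionDataset:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_frames = meta.n_frames
    dt = 1.0 / meta.fps
    frame_t = np.arange(n_frames) * dt
    # positions at frame times (trajectory is frame-sampled by construction,
    # but interpolate defensively for other sampling)
    fx = np.interp(frame_t, trajectory.t, trajectory.x)
    fy = np.interp(frame_t, trajectory.t, trajectory.y)

    ids = truth.active_ids(session_label)
    cells = truth.cells.loc[ids]
    n_cells = len(cells)

    # shared slow log-OU modulation per correlated block, mean ~1
    blocks = sorted(b for b in cells["block"].unique() if b >= 0)
    block_mod: dict[int, np.ndarray] = {}
    tau = 2.0  # s; slow shared fluctuation
    a = np.exp(-dt / tau)
    b_sd = np.sqrt(1 - a * a)
    for blk in blocks:
        z = np.empty(n_frames)
        z[0] = rng.normal()
        eps = rng.normal(size=n_frames - 1)
        for i in range(1, n_frames):
            z[i] = a * z[i - 1] + b_sd * eps[i - 1]
        block_mod[blk] = np.exp(truth.block_log_sd * z - 0.5 * truth.block_log_sd**2)

    bursts = truth.bursts.get(session_label, ())
    burst_members = []
    for burst in bursts:
        member = rng.random(n_cells) < burst.participation_frac
        burst_members.append(member)

    kernel = calcium_kernel(meta.fps, kernel_rise_s, kernel_decay_s)
    events: dict[str, EventTrain] = {}
    traces = np.empty((n_cells, n_frames))
    for i, (gid, row) in enumerate(cells.iterrows()):
        rate = _cell_rate(row, fx, fy, arena)
        if row["block"] >= 0:
            rate = rate * block_mod[int(row["block"])]
        for burst, member in zip(bursts, burst_members):
            if member[i]:
                lo = int(np.floor(burst.time_s * meta.fps))
                hi = int(np.ceil((burst.time_s + burst.duration_s) * meta.fps))
                rate[lo:hi] = rate[lo:hi] * burst.gain
        counts = rng.poisson(rate * dt)
        n_ev = int(counts.sum())
        if n_ev:
            frames = np.repeat(np.arange(n_frames), counts)
            times = np.sort((frames + rng.random(n_ev)) * dt)
            times = np.minimum(times, meta.duration_s)
        else:
            times = np.empty(0)
        cid = str(i)
        events[cid] = EventTrain(cid, times)
        impulse = counts.astype(float)
        clean = np.convolve(impulse, kernel)[:n_frames]
        traces[i] = clean + rng.normal(0, noise_sigma, n_frames)

    trace_matrix = TraceMatrix(traces, tuple(str(i) for i in range(n_cells)), meta.fps)
    return SessionDataset(meta, trajectory, trace_matrix, events, arena)


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------


def _plant_burst_times(
    rng: np.random.Generator, n: int, duration_s: float, min_sep_s: float, session_s: float,
    edge_s: float = 15.0,
) -> np.ndarray:
    """Draw n burst onset times with pairwise separation >= min_sep_s."""
    usable = session_s - 2 * edge_s
    if n * min_sep_s > usable:
        raise ValidationError("cannot place bursts with requested separation")
    # uniform spacings on the leftover slack, then stack with min separations
    slack = usable - n * min_sep_s
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    onsets = edge_s + np.cumsum(gaps[:-1]) + np.arange(n) * min_sep_s
    return onsets


def make_ground_truth(
    preset: SimPreset,
    n_cells: int,
    arena: ArenaConfig,
    duration_s: float,
    seed: int | np.random.SeedSequence,
) -> GroundTruth:
    """Realise per-cell labels, active sets, bursts and blocks from a preset."""
    if n_cells < 20:
        raise ValidationError("n_cells must be >= 20")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    n_place = int(round(preset.frac_place_cells * n_cells))
    n_object = int(round(preset.frac_object_tuned * n_cells))
    place = np.zeros(n_cells, dtype=bool)
    place[:n_place] = True
    object_tuned = np.zeros(n_cells, dtype=bool)
    object_tuned[:n_object] = True  # object-tuned cells are place-tuned at an object

    tx = rng.uniform(0.05 * arena.width_cm, 0.95 * arena.width_cm, n_cells)
    ty = rng.uniform(0.05 * arena.height_cm, 0.95 * arena.height_cm, n_cells)
    if n_object and arena.object_positions:
        objs = np.asarray(arena.object_positions)
        pick = rng.integers(0, len(objs), n_object)
        jitter = rng.normal(0, 1.5, size=(n_object, 2))
        centers = np.clip(
            objs[pick] + jitter,
            [0.5, 0.5],
            [arena.width_cm - 0.5, arena.height_cm - 0.5],
        )
        tx[:n_object], ty[:n_object] = centers[:, 0], centers[:, 1]
    gains = np.where(object_tuned, preset.object_gain, preset.place_gain)
    base = preset.base_rate_hz * np.exp(
        rng.normal(0, preset.base_rate_log_sd, n_cells) - 0.5 * preset.base_rate_log_sd**2
    )

    block = np.full(n_cells, -1)
    non_place = np.flatnonzero(~place)
    needed = preset.n_blocks * preset.block_size
    if needed and needed <= len(non_place):
        chosen = rng.choice(non_place, size=needed, replace=False)
        for b in range(preset.n_blocks):
            block[chosen[b * preset.block_size : (b + 1) * preset.block_size]] = b

    cells = pd.DataFrame(
        {
            "place_cell": place,
            "tuning_x": tx,
            "tuning_y": ty,
            "tuning_width_cm": preset.tuning_width_cm,
            "peak_gain": gains,
            "object_tuned": object_tuned,
            "base_rate_hz": base,
            "block": block,
        },
        index=pd.RangeIndex(n_cells, name="global_id"),
    )

    overlap = {tuple(k): float(v) for k, v in preset.session_overlap.items()}
    active = pd.DataFrame(False, index=cells.index, columns=list(SESSION_LABELS))
    active["HA"] = rng.random(n_cells) < preset.p_active_ha
    for earlier, later in SESSION_PAIRS:
        frac = overlap[(earlier, later)]
        stay = active[earlier] & (rng.random(n_cells) < frac)
        recruit = ~active[earlier] & (rng.random(n_cells) < preset.recruit_prob)
        active[later] = stay | recruit

    bursts: dict[str, tuple[PlantedBurst, ...]] = {}
    for session in SESSION_LABELS:
        n_b = int(preset.burst_counts.get(session, 0))
        onsets = _plant_burst_times(
            rng, n_b, preset.burst_duration_s, preset.burst_min_separation_s, duration_s
        )
        bursts[session] = tuple(
            PlantedBurst(float(t0), preset.burst_duration_s, preset.burst_participation, preset.burst_gain)
            for t0 in onsets
        )

    return GroundTruth(cells, active, bursts, overlap, block_log_sd=preset.block_log_sd)


def registration_from_truth(truth: GroundTruth) -> RegistrationMap:
    """Registration table implied by the planned active sets.

    Per-session indices are assigned 0..n-1 in global-id order, matching
    ``simulate_session``; absent cells get the NA sentinel.
    """
    table = pd.DataFrame(
        pd.NA, index=truth.active.index, columns=list(SESSION_LABELS), dtype="Int64"
    )
    for session in SESSION_LABELS:
        ids = truth.active_ids(session)
        table.loc[ids, session] = np.arange(len(ids))
    table.index.name = "global_id"
    return RegistrationMap(table)


def simulate_study(
    preset: SimPreset | str,
    n_cells: int = 200,
    seed: int = 0,
    animal_id: str = "sim",
    arena: ArenaConfig | None = None,
    fps: float = 20.0,
    duration_s: float = 600.0,
) -> tuple[dict[str, SessionDataset], RegistrationMap, GroundTruth]:
    """Simulate the full four-session study for one animal."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    if arena is None:
        arena = ArenaConfig(object_positions=((10.0, 20.0), (30.0, 20.0)))
    root = np.random.SeedSequence(seed)
    truth_ss, *session_ss = root.spawn(1 + 2 * len(SESSION_LABELS))
    truth = make_ground_truth(preset, n_cells, arena, duration_s, truth_ss)
    group = "vehicle" if preset.name == "vehicle_like" else "antagonist"
    sessions: dict[str, SessionDataset] = {}
    for k, label in enumerate(SESSION_LABELS):
        meta = RecordingMeta(
            session_label=label, animal_id=animal_id, group_label=group,
            fps=fps, duration_s=duration_s,
        )
        traj = simulate_trajectory(arena, meta, seed=np.random.default_rng(session_ss[2 * k]))
        sessions[label] = simulate_session_in_arena(
            truth, label, traj, meta, arena, seed=session_ss[2 * k + 1],
            noise_sigma=preset.noise_sigma,
            kernel_rise_s=preset.kernel_rise_s, kernel_decay_s=preset.kernel_decay_s,
        )
    return sessions, registration_from_truth(truth), truth


def write_study(
    out_dir: str | Path,
    sessions: Mapping[str, SessionDataset],
    regmap: RegistrationMap,
    truth: GroundTruth | None = None,
) -> Path:
    """Write a study tree: one directory per session plus registration and
    ground-truth sidecars.  Returns the study manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"sessions": {}}
    for label, ds in sessions.items():
        write_session(ds, out_dir / label)
        manifest["sessions"][label] = f"{label}/session.yaml"
    regmap.to_csv(out_dir / "registration.csv")
    manifest["registration"] = "registration.csv"
    if truth is not None:
        truth.cells.to_csv(out_dir / "ground_truth_cells.csv")
        rows = [
            (s, b.time_s, b.duration_s, b.participation_frac, b.gain)
            for s, bs in truth.bursts.items()
            for b in bs
        ]
        pd.DataFrame(
            rows, columns=["session", "time_s", "duration_s", "participation_frac", "gain"]
        ).to_csv(out_dir / "ground_truth_bursts.csv", index=False)
        overlap = pd.DataFrame(
            [(a, b, f) for (a, b), f in truth.session_overlap.items()],
            columns=["earlier", "later", "fraction"],
        )
        overlap.to_csv(out_dir / "ground_truth_overlap.csv", index=False)
    path = out_dir / "study.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
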