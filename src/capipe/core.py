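"""Domain types, configuration, and on-disk readers/writers shared by every stage.

Conventions
-----------
Coordinates use the arena's lower-left corner as origin, x rightwards and
y upwards, in centimetres.  Spatial bin ``(i, j)`` (column, row; 0-based)
covers the half-open square ``[i*w, (i+1)*w) x [j*h, (j+1)*h)``; the top and
right arena edges are closed so every in-bounds point maps to exactly one bin.
Times are in seconds, rates in events per second.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SESSION_LABELS = ("HA", "S1", "S2", "S3")
#: Sentinel used in registration CSVs for a cell not found in a session.
ABSENT = "NA"


class ValidationError(ValueError):
    """Raised when an artifact violates one of its invariants."""


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArenaConfig:
    """Open-field arena geometry and spatial binning.

    Defaults describe a 40 x 40 cm arena divided into a 10 x 10 grid of
    ~4 x 4 cm bins, with object-exploration scored within a ~2 cm radius
    of each object's position.
    """

    width_cm: float = 40.0
    height_cm: float = 40.0
    object_positions: tuple[tuple[float, float], ...] = ()
    object_radius_cm: float = 2.0
    n_bins_x: int = 10
    n_bins_y: int = 10

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValidationError("arena dimensions must be positive")
        if self.n_bins_x < 1 or self.n_bins_y < 1:
            raise ValidationError("bin counts must be >= 1")
        if self.object_radius_cm <= 0:
            raise ValidationError("object radius must be positive")
        for ox, oy in self.object_positions:
            if not (0 <= ox <= self.width_cm and 0 <= oy <= self.height_cm):
                raise ValidationError(f"object at ({ox}, {oy}) lies outside the arena")
        object.__setattr__(
            self, "object_positions", tuple((float(a), float(b)) for a, b in self.object_positions)
        )

    @property
    def bin_width_cm(self) -> float:
        return self.width_cm / self.n_bins_x

    @property
    def bin_height_cm(self) -> float:
        return self.height_cm / self.n_bins_y

    @property
    def bin_area_cm2(self) -> float:
        return self.bin_width_cm * self.bin_height_cm

    def bin_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map positions to (col, row) bin indices; right/top edges closed."""
        ix = np.clip(np.floor(np.asarray(x) / self.bin_width_cm).astype(int), 0, self.n_bins_x - 1)
        iy = np.clip(np.floor(np.asarray(y) / self.bin_height_cm).astype(int), 0, self.n_bins_y - 1)
        return ix, iy

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = (np.arange(self.n_bins_x) + 0.5) * self.bin_width_cm
        cy = (np.arange(self.n_bins_y) + 0.5) * self.bin_height_cm
        return cx, cy


@dataclass(frozen=True)
class RecordingMeta:
    """Per-session recording metadata (20 frames/s, 10 min sessions)."""

    session_label: str
    animal_id: str = "animal"
    group_label: str = "vehicle"
    fps: float = 20.0
    duration_s: float = 600.0

    def __post_init__(self) -> None:
        if self.session_label not in SESSION_LABELS:
            raise ValidationError(
                f"session_label must be one of {SESSION_LABELS}, got {self.session_label!r}"
            )
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValidationError("fps and duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class BurstConfig:
    z_threshold: float = 2.0
    min_duration_s: float = 0.05


@dataclass
class SpatialConfig:
    downsample_dt_s: float = 0.5
    gaussian_sigma_bins: float = 1.0
    n_shuffles: int = 500
    alpha: float = 0.05
    min_events: int = 20
    field_threshold_frac: float = 0.2
    object_pad_bins: int = 2
    min_shift_s: float = 10.0


@dataclass
class NetworkConfig:
    edge_alpha: float = 0.001
    correction: str = "bonferroni"
    positive_only: bool = True
    distance: str = "inverse"  # edge length 1/r; "one_minus_r" available


@dataclass
class AnalysisConfig:
    """All numeric analysis parameters, grouped per stage."""

    burst: BurstConfig = field(default_factory=BurstConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    min_active_events: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.spatial.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if not (0 < self.network.edge_alpha < 1):
            raise ValidationError("edge_alpha must be in (0, 1)")
        for name, v in [
            ("z_threshold", self.burst.z_threshold),
            ("min_duration_s", self.burst.min_duration_s),
            ("downsample_dt_s", self.spatial.downsample_dt_s),
            ("gaussian_sigma_bins", self.spatial.gaussian_sigma_bins),
            ("n_shuffles", self.spatial.n_shuffles),
            ("min_events", self.spatial.min_events),
            ("field_threshold_frac", self.spatial.field_threshold_frac),
        ]:
            if v <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        kwargs = {}
        for name, sub in [("burst", BurstConfig), ("spatial", SpatialConfig), ("network", NetworkConfig)]:
            if name in raw:
                kwargs[name] = sub(**raw[name])
        for key in ("min_active_events", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time-stamped 2-D positions with optional derived speed (cm/s)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if len(self.t) == 0:
            raise ValidationError("trajectory is empty")
        if np.any(~np.isfinite(self.t)) or np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValidationError("trajectory contains non-finite values")
        if self.t[0] < 0:
            raise ValidationError("negative timestamps")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
            if len(self.speed) != len(self.t):
                raise ValidationError("speed length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def clipped_to(self, arena: ArenaConfig) -> "Trajectory":
        """Return a copy with positions clipped to the arena bounds."""
        return Trajectory(
            self.t,
            np.clip(self.x, 0.0, arena.width_cm),
            np.clip(self.y, 0.0, arena.height_cm),
            self.speed,
        )


@dataclass
class EventTrain:
    """Deconvolved calcium transients of one cell, treated as spike events."""

    cell_id: str
    event_times: np.ndarray
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if np.any(~np.isfinite(self.event_times)):
            raise ValidationError(f"cell {self.cell_id}: non-finite event times")
        if np.any(np.diff(self.event_times) < 0):
            raise ValidationError(f"cell {self.cell_id}: event times not sorted")
        if len(self.event_times) and self.event_times[0] < 0:
            raise ValidationError(f"cell {self.cell_id}: negative event time")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if len(self.amplitudes) != len(self.event_times):
                raise ValidationError(f"cell {self.cell_id}: amplitude length mismatch")

    @property
    def n_events(self) -> int:
        return len(self.event_times)


@dataclass
class TraceMatrix:
    """Cells x frames matrix of dF/F fluorescence traces."""

    values: np.ndarray
    cell_ids: tuple[str, ...]
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = tuple(str(c) for c in self.cell_ids)
        if self.values.ndim != 2:
            raise ValidationError("trace matrix must be 2-D (cells x frames)")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValidationError("row count does not match cell_ids")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("trace matrix contains non-finite values")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class SessionDataset:
    """Everything recorded in one session of one animal."""

    meta: RecordingMeta
    trajectory: Trajectory
    traces: TraceMatrix
    events: dict[str, EventTrain]
    arena: ArenaConfig

    def __post_init__(self) -> None:
        one_frame = 1.0 / self.meta.fps
        if abs(self.traces.duration_s - self.meta.duration_s) > one_frame + 1e-9:
            raise ValidationError(
                f"trace duration {self.traces.duration_s:.2f} s does not match "
                f"session duration {self.meta.duration_s:.2f} s"
            )
        if abs(self.trajectory.t[-1] - self.meta.duration_s) > max(one_frame, 1.0) + 1e-9:
            raise ValidationError(
                f"trajectory span {self.trajectory.t[-1]:.2f} s does not match "
                f"session duration {self.meta.duration_s:.2f} s"
            )
        for cid, train in self.events.items():
            if train.n_events and train.event_times[-1] > self.meta.duration_s + 1e-9:
                raise ValidationError(f"cell {cid}: event beyond session end")

    @property
    def cell_ids(self) -> tuple[str, ...]:
        return self.traces.cell_ids


class RegistrationMap:
    """Longitudinal cell registration: global id <-> per-session cell index.

    The habituation session is the reference.  Internally a DataFrame indexed
    by ``global_id`` with one nullable-integer column per session; missing
    entries mean the cell was not detected in that session.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [s for s in SESSION_LABELS if s not in table.columns]
        if missing:
            raise ValidationError(f"registration table missing sessions {missing}")
        extra = [c for c in table.columns if c not in SESSION_LABELS]
        if extra:
            raise ValidationError(f"unknown session label(s) {extra}")
        table = table[list(SESSION_LABELS)].astype("Int64")
        for s in SESSION_LABELS:
            col = table[s].dropna()
            if col.duplicated().any():
                dup = int(col[col.duplicated()].iloc[0])
                raise ValidationError(f"session {s}: index {dup} mapped to multiple global ids")
        self.table = table

    def __eq__(self, other) -> bool:
        return isinstance(other, RegistrationMap) and self.table.equals(other.table)

    @property
    def global_ids(self) -> pd.Index:
        return self.table.index

    def present(self, session: str) -> pd.Series:
        """Global ids present in ``session`` -> their per-session index."""
        if session not in SESSION_LABELS:
            raise ValidationError(f"unknown session {session!r}")
        return self.table[session].dropna().astype(int)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.reset_index().rename(columns={"index": "global_id"})
        if out.columns[0] != "global_id":
            out = out.rename(columns={out.columns[0]: "global_id"})
        out.to_csv(path, index=False, na_rep=ABSENT)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegistrationMap":
        df = pd.read_csv(path, na_values=[ABSENT], keep_default_na=False)
        if "global_id" not in df.columns:
            raise ValidationError("registration CSV must have a global_id column")
        df = df.set_index("global_id")
        return cls(df)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def compute_speed(trajectory: Trajectory, smooth_window_s: float = 0.5) -> Trajectory:
    """Fill per-sample speed (cm/s) by finite differences.

    ``speed[i]`` is the Euclidean step from sample ``i-1`` to ``i`` divided by
    the time step; the first sample copies the second.  A centred moving
    average of ``smooth_window_s`` (set 0 to disable) removes tracking jitter.
    """
    if len(trajectory) < 2:
        raise ValidationError("need at least 2 samples to compute speed")
    dt = np.diff(trajectory.t)
    step = np.hypot(np.diff(trajectory.x), np.diff(trajectory.y))
    speed = np.empty(len(trajectory))
    speed[1:] = step / dt
    speed[0] = speed[1]
    if smooth_window_s and smooth_window_s > 0:
        median_dt = float(np.median(dt))
        win = max(1, int(round(smooth_window_s / median_dt)))
        if win > 1:
            kernel = np.ones(win) / win
            pad = win // 2
            padded = np.pad(speed, pad, mode="edge")
            speed = np.convolve(padded, kernel, mode="same")[pad : pad + len(trajectory)]
    return Trajectory(trajectory.t, trajectory.x, trajectory.y, speed)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"t": trajectory.t, "x": trajectory.x, "y": trajectory.y}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"trajectory CSV missing column {col!r}")
    return Trajectory(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy())


def write_events(events: Mapping[str, EventTrain], path: str | Path) -> None:
    rows = []
    for cid in events:
        tr = events[cid]
        amps = tr.amplitudes if tr.amplitudes is not None else np.ones(tr.n_events)
        for t, a in zip(tr.event_times, amps):
            rows.append((cid, t, a))
    pd.DataFrame(rows, columns=["cell_id", "time_s", "amplitude"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_events(path: str | Path, cell_ids: Sequence[str] | None = None) -> dict[str, EventTrain]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    for col in ("cell_id", "time_s"):
        if col not in df.columns:
            raise ValidationError(f"event CSV missing column {col!r}")
    if np.any(~np.isfinite(df["time_s"].to_numpy())) or (df["time_s"] < 0).any():
        raise ValidationError("event CSV contains invalid times")
    out: dict[str, EventTrain] = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        amps = grp["amplitude"].to_numpy() if "amplitude" in grp.columns else None
        out[str(cid)] = EventTrain(str(cid), grp["time_s"].to_numpy(), amps)
    if cell_ids is not None:
        for cid in cell_ids:  # cells with zero events still get a train
            out.setdefault(str(cid), EventTrain(str(cid), np.empty(0)))
        out = {cid: out[cid] for cid in map(str, cell_ids)}
    return out


def write_traces(traces: TraceMatrix, path: str | Path) -> None:
    """Write traces; ``.h5``/``.hdf5`` -> HDF5, otherwise wide CSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("traces", data=traces.values)
            ds.attrs["fps"] = traces.fps
            fh.create_dataset(
                "cell_ids", data=np.array(traces.cell_ids, dtype=h5py.string_dtype())
            )
    else:
        df = pd.DataFrame(traces.values, index=pd.Index(traces.cell_ids, name="cell_id"))
        df.insert(0, "fps", traces.fps)
        df.to_csv(path)


def read_traces(path: str | Path) -> TraceMatrix:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            values = fh["traces"][:]
            fps = float(fh["traces"].attrs["fps"])
            cell_ids = tuple(c.decode() if isinstance(c, bytes) else str(c) for c in fh["cell_ids"][:])
        return TraceMatrix(values, cell_ids, fps)
    df = pd.read_csv(path, index_col=0)
    fps = float(df["fps"].iloc[0])
    values = df.drop(columns=["fps"]).to_numpy()
    return TraceMatrix(values, tuple(str(i) for i in df.index), fps)


def write_session(dataset: SessionDataset, out_dir: str | Path) -> Path:
    """Write one session as a manifest tree; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_trajectory(dataset.trajectory, out_dir / "trajectory.csv")
    write_events(dataset.events, out_dir / "events.csv")
    write_traces(dataset.traces, out_dir / "traces.h5")
    manifest = {
        "meta": {
            "session_label": dataset.meta.session_label,
            "animal_id": dataset.meta.animal_id,
            "group_label": dataset.meta.group_label,
            "fps": float(dataset.meta.fps),
            "duration_s": float(dataset.meta.duration_s),
        },
        "arena": {
            "width_cm": dataset.arena.width_cm,
            "height_cm": dataset.arena.height_cm,
            "object_positions": [list(p) for p in dataset.arena.object_positions],
            "object_radius_cm": dataset.arena.object_radius_cm,
            "n_bins_x": dataset.arena.n_bins_x,
            "n_bins_y": dataset.arena.n_bins_y,
        },
        "files": {"trajectory": "trajectory.csv", "events": "events.csv", "traces": "traces.h5"},
    }
    manifest_path = out_dir / "session.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_session(manifest_path: str | Path) -> SessionDataset:
    """Read and validate one session from its YAML manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    files = manifest["files"]
    for key in ("trajectory", "events", "traces"):
        if not (base / files[key]).exists():
            raise FileNotFoundError(base / files[key])
    meta = RecordingMeta(**manifest["meta"])
    arena_raw = dict(manifest["arena"])
    arena_raw["object_positions"] = tuple(tuple(p) for p in arena_raw.get("object_positions", ()))
    arena = ArenaConfig(**arena_raw)
    trajectory = read_trajectory(base / files["trajectory"])
    traces = read_traces(base / files["traces"])
    events = read_events(base / files["events"], cell_ids=traces.cell_ids)
    return SessionDataset(meta, trajectory, traces, events, arena)


def read_registration(path: str | Path) -> RegistrationMap:
    return RegistrationMap.from_csv(path)
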