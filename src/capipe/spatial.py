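"""Place-cell-like classification and spatial firing metrics.

The trajectory is down-sampled to 0.5 s windows and the arena divided into a
10 x 10 grid (~4 x 4 cm bins).  Each deconvolved event is assigned to the bin
of its window's mean position.  Spatial selectivity is the Skaggs information
(bits/event); significance comes from a circular-shuffle null in which the
whole event train is rotated in time by a random offset while the behavioural
record stays fixed.  A cell is place-cell-like when the empirical p-value is
below alpha AND it emitted at least ``min_events`` events.  Fields are
contiguous regions above 20% of the smoothed peak rate; coherence is the
Fisher-z of the correlation between each visited bin's raw rate and the mean
rate of its visited neighbours; the object score is the overlap of field bins
with a 2-bin-padded object mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ArenaConfig, EventTrain, SpatialConfig, Trajectory, ValidationError

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class RateMapBundle:
    """Occupancy, spike counts and rate grids, all shaped (n_bins_x, n_bins_y)."""

    spike_counts: np.ndarray
    occupancy_time_s: np.ndarray
    visited_mask: np.ndarray
    raw_rate: np.ndarray
    arena: ArenaConfig
    visited_proportion: float
    smoothed_rate: np.ndarray | None = None
    smoothed_spike: np.ndarray | None = None
    smoothed_occupancy: np.ndarray | None = None
    n_events: int = 0


@dataclass
class PlaceField:
    bins: list[tuple[int, int]]
    centroid_cm: tuple[float, float]
    size_cm2: float


@dataclass
class SpatialCellResult:
    cell_id: str
    n_events: int
    info_bits_per_event: float
    p_value: float
    is_place_cell_like: bool
    fields: list[PlaceField] = field(default_factory=list)
    coherence_z: float = np.nan
    object_score: float = np.nan


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


class _Binning:
    """Window-level spatial down-sampling shared by all cells of a session."""

    def __init__(self, trajectory: Trajectory, arena: ArenaConfig, dt: float):
        if dt <= 0:
            raise ValidationError("downsample dt must be positive")
        t0 = trajectory.t[0]
        span = trajectory.t[-1] - t0
        n_win = int(np.floor(span / dt + 1e-9))
        if n_win < 1:
            raise ValidationError("trajectory shorter than one down-sampling window")
        win_of_sample = np.floor((trajectory.t - t0) / dt).astype(int)
        inside = win_of_sample < n_win
        wx = np.bincount(win_of_sample[inside], weights=trajectory.x[inside], minlength=n_win)
        wy = np.bincount(win_of_sample[inside], weights=trajectory.y[inside], minlength=n_win)
        cnt = np.bincount(win_of_sample[inside], minlength=n_win)
        if np.any(cnt == 0):
            raise ValidationError("trajectory has gaps longer than one window")
        ix, iy = arena.bin_of(wx / cnt, wy / cnt)
        self.arena = arena
        self.dt = dt
        self.t0 = float(t0)
        self.n_win = n_win
        self.flat_bin = ix * arena.n_bins_y + iy  # per-window flat bin id
        n_bins = arena.n_bins_x * arena.n_bins_y
        self.occupancy = np.bincount(self.flat_bin, minlength=n_bins) * dt
        self.span = n_win * dt

    def window_of(self, times: np.ndarray, strict: bool = True) -> np.ndarray:
        rel = np.asarray(times, dtype=float) - self.t0
        win = np.floor(rel / self.dt).astype(int)
        ok = (rel >= 0) & (win < self.n_win)
        # events right at the session end belong to the last window
        at_end = (win == self.n_win) & (rel <= self.span + 1e-9)
        win[at_end] = self.n_win - 1
        ok |= at_end
        if not ok.all():
            if strict:
                warnings.warn(f"dropping {int((~ok).sum())} event(s) outside the tracked span")
            win = win[ok]
        return win

    def spike_counts(self, event_times: np.ndarray) -> np.ndarray:
        win = self.window_of(event_times)
        n_bins = self.arena.n_bins_x * self.arena.n_bins_y
        return np.bincount(self.flat_bin[win], minlength=n_bins)


def bin_session(
    trajectory: Trajectory,
    events: EventTrain,
    arena: ArenaConfig,
    dt: float = 0.5,
) -> RateMapBundle:
    """Raw rate-map bundle for one cell.

    Positions are averaged per ``dt`` window; each event is assigned to the
    bin of its window; occupancy is ``dt`` times the window count per bin.
    """
    binning = _Binning(trajectory, arena, dt)
    return _bundle_from_counts(binning, binning.spike_counts(events.event_times))


def _bundle_from_counts(binning: _Binning, flat_counts: np.ndarray) -> RateMapBundle:
    arena = binning.arena
    shape = (arena.n_bins_x, arena.n_bins_y)
    counts = flat_counts.reshape(shape).astype(float)
    occ = binning.occupancy.reshape(shape)
    visited = occ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(visited, counts / np.where(visited, occ, 1.0), 0.0)
    return RateMapBundle(
        spike_counts=counts,
        occupancy_time_s=occ,
        visited_mask=visited,
        raw_rate=rate,
        arena=arena,
        visited_proportion=float(visited.mean()),
        n_events=int(counts.sum()),
    )


def bundle_from_grids(
    spike_counts: np.ndarray, occupancy_time_s: np.ndarray, arena: ArenaConfig
) -> RateMapBundle:
    """Build a bundle directly from spike-count and occupancy grids."""
    counts = np.asarray(spike_counts, dtype=float)
    occ = np.asarray(occupancy_time_s, dtype=float)
    if counts.shape != occ.shape or counts.shape != (arena.n_bins_x, arena.n_bins_y):
        raise ValidationError("grids must share the arena's bin shape")
    if np.any(occ < 0) or np.any(counts < 0):
        raise ValidationError("grids must be non-negative")
    visited = occ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(visited, counts / np.where(visited, occ, 1.0), 0.0)
    return RateMapBundle(
        spike_counts=counts,
        occupancy_time_s=occ,
        visited_mask=visited,
        raw_rate=rate,
        arena=arena,
        visited_proportion=float(visited.mean()),
        n_events=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# Smoothing, information, significance
# ---------------------------------------------------------------------------


def smooth_rate_map(bundle: RateMapBundle, sigma_bins: float = 1.0) -> RateMapBundle:
    """Gaussian-smooth spike and occupancy histograms, then divide.

    Kernel sigma is in bins, truncated at 3 sigma; dividing the two smoothed
    histograms renormalises the kernel at the arena edges.  Bins whose
    smoothed occupancy is zero stay undefined (NaN).
    """
    if not bundle.visited_mask.any():
        raise ValidationError("cannot smooth an all-unvisited map")
    gs = ndimage.gaussian_filter(bundle.spike_counts, sigma_bins, mode="constant", truncate=3.0)
    go = ndimage.gaussian_filter(bundle.occupancy_time_s, sigma_bins, mode="constant", truncate=3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(go > 0, gs / np.where(go > 0, go, 1.0), np.nan)
    bundle.smoothed_spike = gs
    bundle.smoothed_occupancy = go
    bundle.smoothed_rate = smoothed
    return bundle


def skaggs_information(bundle: RateMapBundle, smoothed: bool = False) -> float:
    """Skaggs spatial information in bits per event.

    I = sum_i p_i (lam_i / lam_bar) log2(lam_i / lam_bar), with p_i the
    occupancy share of bin i, lam_i its firing rate and lam_bar the
    occupancy-weighted mean rate.  Zero-rate bins contribute zero.
    """
    if smoothed:
        if bundle.smoothed_rate is None:
            raise ValidationError("smoothed rate not computed")
        rate = np.where(np.isfinite(bundle.smoothed_rate), bundle.smoothed_rate, 0.0)
        occ = bundle.smoothed_occupancy
    else:
        rate = bundle.raw_rate
        occ = bundle.occupancy_time_s
    total_occ = occ.sum()
    if total_occ <= 0:
        raise ValidationError("zero total occupancy")
    p = occ / total_occ
    mean_rate = float((p * rate).sum())
    if mean_rate <= 0:
        raise ValidationError("zero mean rate: no events")
    ratio = rate / mean_rate
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def _info_from_counts(counts: np.ndarray, occupancy: np.ndarray) -> np.ndarray:
    """Vectorised Skaggs information for stacked count vectors (k, n_bins)."""
    total_occ = occupancy.sum()
    p = occupancy / total_occ
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupancy > 0, counts / np.where(occupancy > 0, occupancy, 1.0), 0.0)
    mean_rate = rate @ p
    ratio = rate / mean_rate[:, None]
    term = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return term.sum(axis=1)


def shuffle_p_value(
    trajectory: Trajectory,
    events: EventTrain,
    arena: ArenaConfig,
    n_shuffles: int = 500,
    seed: int | np.random.Generator = 0,
    dt: float = 0.5,
    min_shift_s: float = 10.0,
) -> tuple[float, float]:
    """Circular-shuffle significance of a cell's spatial information.

    The whole event train is rotated in time modulo the tracked span by
    offsets drawn uniformly from [min_shift, T - min_shift]; the empirical
    p-value is the proportion of shuffled information scores that equal or
    exceed the observed score.  Returns ``(observed_info, p_value)``.
    """
    if events.n_events == 0:
        raise ValidationError("cannot shuffle a cell with no events")
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    binning = _Binning(trajectory, arena, dt)
    return _shuffle_p_from_binning(binning, events.event_times, n_shuffles, seed, min_shift_s)


def _shuffle_p_from_binning(
    binning: _Binning,
    event_times: np.ndarray,
    n_shuffles: int,
    seed: int | np.random.Generator,
    min_shift_s: float,
) -> tuple[float, float]:
    T = binning.span
    if T <= 2 * min_shift_s:
        raise ValidationError(
            f"session span {T:.1f} s too short for a {min_shift_s:.1f} s minimum rotation"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = len(binning.occupancy)

    flat = binning.flat_bin
    obs_counts = np.bincount(flat[binning.window_of(event_times)], minlength=n_bins)
    observed = float(_info_from_counts(obs_counts[None, :], binning.occupancy)[0])

    rel = np.asarray(event_times, dtype=float) - binning.t0
    rel = rel[(rel >= 0) & (rel <= T + 1e-9)]
    offsets = rng.uniform(min_shift_s, T - min_shift_s, size=n_shuffles)
    shifted = np.mod(rel[None, :] + offsets[:, None], T)
    win = np.minimum((shifted / binning.dt).astype(int), binning.n_win - 1)
    bins = flat[win]
    counts = np.zeros((n_shuffles, n_bins))
    rows = np.repeat(np.arange(n_shuffles), bins.shape[1])
    np.add.at(counts, (rows, bins.ravel()), 1.0)
    shuffled = _info_from_counts(counts, binning.occupancy)
    p = float(np.count_nonzero(shuffled >= observed) / n_shuffles)
    return observed, p


def classify(p_value: float, n_events: int, config: SpatialConfig | None = None) -> bool:
    """Place-cell-like flag: significant information AND adequate sampling."""
    config = config or SpatialConfig()
    return (p_value < config.alpha) and (n_events >= config.min_events)


# ---------------------------------------------------------------------------
# Fields, coherence, object score
# ---------------------------------------------------------------------------


def extract_fields(
    smoothed_rate: np.ndarray, arena: ArenaConfig, threshold_frac: float = 0.2
) -> list[PlaceField]:
    """Contiguous (4-connected) regions at or above ``threshold_frac`` of peak.

    Multiple fields are allowed; each field records its bin set, the
    unweighted centroid of its bin centres (cm) and its area in cm^2.
    """
    rate = np.where(np.isfinite(smoothed_rate), smoothed_rate, 0.0)
    peak = rate.max()
    if peak <= 0:
        raise ValidationError("empty rate map: no peak to threshold")
    supra = rate >= threshold_frac * peak
    labels, n_fields = ndimage.label(supra, structure=_FOUR_CONN)
    cx, cy = arena.bin_centers()
    fields = []
    for k in range(1, n_fields + 1):
        ii, jj = np.nonzero(labels == k)
        centroid = (float(cx[ii].mean()), float(cy[jj].mean()))
        fields.append(
            PlaceField(
                bins=list(zip(ii.tolist(), jj.tolist())),
                centroid_cm=centroid,
                size_cm2=len(ii) * arena.bin_area_cm2,
            )
        )
    return fields


def spatial_coherence(bundle: RateMapBundle) -> float:
    """Fisher-z of the correlation between raw rate and neighbour-mean rate.

    The box-car value at a visited bin is the mean raw rate of its visited
    3x3 neighbours (centre excluded); the Pearson correlation is taken over
    visited bins with at least one visited neighbour.
    """
    rate = bundle.raw_rate
    visited = bundle.visited_mask
    if visited.sum() < 3:
        raise ValidationError("need at least 3 visited bins for coherence")
    vr = np.where(visited, rate, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    neigh_sum = ndimage.convolve(vr, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(visited.astype(float), kernel, mode="constant", cval=0.0)
    use = visited & (neigh_cnt > 0)
    a = rate[use]
    b = neigh_sum[use] / neigh_cnt[use]
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("coherence undefined for a constant rate map")
    r = float(np.corrcoef(a, b)[0, 1])
    r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    return float(np.arctanh(r))


def object_mask(arena: ArenaConfig, pad_bins: int = 2) -> np.ndarray:
    """Union of (2*pad+1)-square neighbourhoods around each object's bin."""
    mask = np.zeros((arena.n_bins_x, arena.n_bins_y), dtype=bool)
    for ox, oy in arena.object_positions:
        ix, iy = arena.bin_of(np.array([ox]), np.array([oy]))
        i, j = int(ix[0]), int(iy[0])
        mask[
            max(0, i - pad_bins) : min(arena.n_bins_x, i + pad_bins + 1),
            max(0, j - pad_bins) : min(arena.n_bins_y, j + pad_bins + 1),
        ] = True
    return mask


def object_score(fields: list[PlaceField], mask: np.ndarray) -> float:
    """Fraction of the cell's pooled field bins lying inside the object mask."""
    if not fields:
        raise ValidationError("object score undefined without fields")
    bins = {b for f in fields for b in f.bins}
    inside = sum(1 for (i, j) in bins if mask[i, j])
    return inside / len(bins)


# ---------------------------------------------------------------------------
# Per-session driver
# ---------------------------------------------------------------------------


def analyze_session_cells(
    trajectory: Trajectory,
    events: dict[str, EventTrain],
    arena: ArenaConfig,
    config: SpatialConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[SpatialCellResult]:
    """Full spatial characterisation of every cell in a session.

    Cells with zero events are reported with NaN information and p = 1.
    Field extraction, coherence and the object score are computed for every
    cell with events; classification applies the significance + sampling
    criteria.
    """
    config = config or SpatialConfig()
    binning = _Binning(trajectory, arena, config.downsample_dt_s)
    mask = object_mask(arena, config.object_pad_bins) if arena.object_positions else None
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(len(events))
    results = []
    for cs, (cid, train) in zip(cell_seeds, sorted(events.items(), key=lambda kv: kv[0])):
        n_ev = train.n_events
        if n_ev == 0:
            results.append(SpatialCellResult(cid, 0, np.nan, 1.0, False))
            continue
        info, p = _shuffle_p_from_binning(
            binning, train.event_times, config.n_shuffles,
            np.random.default_rng(cs), config.min_shift_s,
        )
        bundle = _bundle_from_counts(binning, binning.spike_counts(train.event_times))
        smooth_rate_map(bundle, config.gaussian_sigma_bins)
        fields = extract_fields(bundle.smoothed_rate, arena, config.field_threshold_frac)
        try:
            coh = spatial_coherence(bundle)
        except ValidationError:
            coh = np.nan
        score = object_score(fields, mask) if (mask is not None and fields) else np.nan
        results.append(
            SpatialCellResult(
                cell_id=cid,
                n_events=n_ev,
                info_bits_per_event=info,
                p_value=p,
                is_place_cell_like=classify(p, n_ev, config),
                fields=fields,
                coherence_z=coh,
                object_score=score,
            )
        )
    return results


def spatial_table(
    results: list[SpatialCellResult], animal_id: str, session: str
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": animal_id,
                "session": session,
                "cell_id": r.cell_id,
                "n_events": r.n_events,
                "info_bits_per_event": r.info_bits_per_event,
                "p_value": r.p_value,
                "is_place_cell_like": r.is_place_cell_like,
                "n_fields": len(r.fields),
                "total_field_size_cm2": sum(f.size_cm2 for f in r.fields),
                "coherence_z": r.coherence_z,
                "object_score": r.object_score,
            }
            for r in results
        ]
    )
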