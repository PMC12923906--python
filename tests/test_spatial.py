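import numpy as np
import pytest

from capipe.core import ArenaConfig, EventTrain, SpatialConfig, Trajectory, ValidationError
from capipe.spatial import (
    bin_session,
    bundle_from_grids,
    classify,
    extract_fields,
    object_mask,
    object_score,
    shuffle_p_value,
    skaggs_information,
    smooth_rate_map,
    spatial_coherence,
)
from capipe.synthetic import simulate_session_in_arena

from conftest import make_truth


def _uniform_traj(duration=600.0, fps=20.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fps)
    t = np.arange(n) / fps
    return Trajectory(t, rng.uniform(0, 40, n), rng.uniform(0, 40, n))


class TestBinSession:
    def test_confined_animal_single_visited_bin(self):
        n = 1200
        traj = Trajectory(np.arange(n) / 20.0, np.full(n, 2.0), np.full(n, 2.0))
        bundle = bin_session(traj, EventTrain("c", [10.0, 20.0]), ArenaConfig())
        assert bundle.visited_mask.sum() == 1
        assert bundle.visited_proportion == pytest.approx(0.01)
        assert bundle.spike_counts[0, 0] == 2

    def test_occupancy_conserves_session_duration(self):
        traj = _uniform_traj()
        bundle = bin_session(traj, EventTrain("c", [1.0]), ArenaConfig())
        assert bundle.occupancy_time_s.sum() == pytest.approx(600.0, abs=0.5 + 1e-9)

    def test_spike_counts_conserve_in_span_events(self):
        traj = _uniform_traj()
        times = np.sort(np.random.default_rng(1).uniform(0, 599, 150))
        bundle = bin_session(traj, EventTrain("c", times), ArenaConfig())
        assert bundle.spike_counts.sum() == 150

    def test_matches_per_window_assignment_oracle(self):
        arena = ArenaConfig()
        traj = _uniform_traj(duration=60.0, seed=2)
        times = np.sort(np.random.default_rng(3).uniform(0, 59, 40))
        bundle = bin_session(traj, EventTrain("c", times), arena, dt=0.5)
        # direct loop: mean position per 0.5 s window, assign events by window
        n_win = int(np.floor(traj.t[-1] / 0.5))
        occ = np.zeros((10, 10))
        counts = np.zeros((10, 10))
        for w in range(n_win):
            sel = (traj.t >= w * 0.5) & (traj.t < (w + 1) * 0.5)
            mx, my = traj.x[sel].mean(), traj.y[sel].mean()
            i, j = arena.bin_of(np.array([mx]), np.array([my]))
            occ[i[0], j[0]] += 0.5
            counts[i[0], j[0]] += np.count_nonzero((times >= w * 0.5) & (times < (w + 1) * 0.5))
        np.testing.assert_allclose(bundle.occupancy_time_s, occ)
        np.testing.assert_allclose(bundle.spike_counts, counts)


class TestSmoothing:
    def test_uniform_map_unchanged(self):
        arena = ArenaConfig()
        bundle = bundle_from_grids(np.full((10, 10), 4.0), np.full((10, 10), 2.0), arena)
        smooth_rate_map(bundle)
        np.testing.assert_allclose(bundle.smoothed_rate, 2.0, rtol=1e-9)

    def test_tiny_sigma_approaches_raw(self):
        arena = ArenaConfig()
        rng = np.random.default_rng(4)
        bundle = bundle_from_grids(rng.poisson(3, (10, 10)).astype(float), np.full((10, 10), 1.0), arena)
        smooth_rate_map(bundle, sigma_bins=1e-4)
        np.testing.assert_allclose(bundle.smoothed_rate, bundle.raw_rate, atol=1e-9)

    def test_single_central_spike_mass_conserved(self):
        arena = ArenaConfig()
        counts = np.zeros((10, 10))
        counts[5, 5] = 1.0
        bundle = bundle_from_grids(counts, np.full((10, 10), 1.0), arena)
        smooth_rate_map(bundle, sigma_bins=1.0)
        assert bundle.smoothed_spike.sum() == pytest.approx(1.0, abs=1e-6)


class TestSkaggsInformation:
    def test_uniform_rate_zero_bits(self):
        arena = ArenaConfig()
        bundle = bundle_from_grids(np.full((10, 10), 3.0), np.full((10, 10), 2.0), arena)
        assert skaggs_information(bundle) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 4, 16])
    def test_single_active_bin_of_k_gives_log2k(self, k):
        arena = ArenaConfig()
        occ = np.zeros((10, 10))
        counts = np.zeros((10, 10))
        occ.flat[:k] = 5.0
        counts.flat[0] = 7.0
        bundle = bundle_from_grids(counts, occ, arena)
        assert skaggs_information(bundle) == pytest.approx(np.log2(k), abs=1e-12)

    def test_matches_term_by_term_oracle(self):
        arena = ArenaConfig()
        rng = np.random.default_rng(5)
        occ = rng.uniform(0, 3, (10, 10))
        occ[rng.random((10, 10)) < 0.2] = 0.0
        counts = rng.poisson(2, (10, 10)) * (occ > 0)
        bundle = bundle_from_grids(counts.astype(float), occ, arena)
        p = occ / occ.sum()
        rate = np.where(occ > 0, counts / np.maximum(occ, 1e-300), 0.0)
        lam = (p * rate).sum()
        expected = sum(
            p[i, j] * (rate[i, j] / lam) * np.log2(rate[i, j] / lam)
            for i in range(10)
            for j in range(10)
            if rate[i, j] > 0
        )
        assert skaggs_information(bundle) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_on_random_maps(self):
        arena = ArenaConfig()
        rng = np.random.default_rng(6)
        for _ in range(50):
            occ = rng.uniform(0.1, 3, (10, 10))
            counts = rng.poisson(1, (10, 10)).astype(float)
            if counts.sum() == 0:
                continue
            assert skaggs_information(bundle_from_grids(counts, occ, arena)) >= 0

    def test_zero_events_rejected(self):
        arena = ArenaConfig()
        with pytest.raises(ValidationError):
            skaggs_information(bundle_from_grids(np.zeros((10, 10)), np.ones((10, 10)), arena))


class TestShuffle:
    def test_single_shuffle_below_observed_gives_zero(self):
        # strongly place-locked events against a two-bin trajectory
        n = 24000
        t = np.arange(n) / 20.0
        x = np.where(t < 600, 2.0, 38.0)
        traj = Trajectory(t, x, np.full(n, 2.0))
        events = EventTrain("c", np.sort(np.random.default_rng(7).uniform(0, 500, 100)))
        _, p = shuffle_p_value(traj, events, ArenaConfig(), n_shuffles=1, seed=0)
        assert p in (0.0, 1.0)

    def test_strongly_tuned_cell_p_zero(self, arena, meta, ou_trajectory):
        truth = make_truth(1, n_place=1, place_gain=10.0, base_rate_hz=0.4)
        ds = simulate_session_in_arena(truth, "S1", ou_trajectory, meta, arena, seed=8)
        assert ds.events["0"].n_events >= 100
        _, p = shuffle_p_value(ou_trajectory, ds.events["0"], arena, n_shuffles=500, seed=9)
        assert p == 0.0

    def test_short_session_rejected(self):
        n = 200
        traj = Trajectory(np.arange(n) / 20.0, np.full(n, 2.0), np.full(n, 2.0))
        with pytest.raises(ValidationError):
            shuffle_p_value(traj, EventTrain("c", [1.0]), ArenaConfig(), min_shift_s=10.0)

    def test_reproducible_given_seed(self, arena):
        traj = _uniform_traj(seed=10)
        events = EventTrain("c", np.sort(np.random.default_rng(11).uniform(0, 599, 80)))
        a = shuffle_p_value(traj, events, arena, n_shuffles=100, seed=42)
        b = shuffle_p_value(traj, events, arena, n_shuffles=100, seed=42)
        assert a == b


class TestClassify:
    @pytest.mark.parametrize(
        "p,n_events,expected",
        [(0.01, 50, True), (0.01, 19, False), (0.05, 50, False), (0.049, 20, True)],
    )
    def test_joint_criteria(self, p, n_events, expected):
        assert classify(p, n_events, SpatialConfig()) is expected


class TestFields:
    def test_single_nonzero_bin(self):
        arena = ArenaConfig()
        rate = np.zeros((10, 10))
        rate[3, 7] = 2.0
        (field,) = extract_fields(rate, arena)
        assert field.size_cm2 == pytest.approx(16.0)
        assert field.centroid_cm == (pytest.approx(14.0), pytest.approx(30.0))

    def test_plus_shaped_field_from_thresholding(self):
        arena = ArenaConfig(width_cm=20, height_cm=20, n_bins_x=5, n_bins_y=5)
        rate = np.full((5, 5), 1.0)
        rate[2, 2] = 10.0
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rate[2 + di, 2 + dj] = 3.0
        fields = extract_fields(rate, arena, threshold_frac=0.2)
        assert len(fields) == 1
        assert fields[0].size_cm2 == pytest.approx(5 * 16.0)
        assert sorted(fields[0].bins) == sorted(
            [(2, 2), (3, 2), (1, 2), (2, 3), (2, 1)]
        )

    def test_disconnected_corners_give_two_fields(self):
        arena = ArenaConfig()
        rate = np.zeros((10, 10))
        rate[0, 0] = 5.0
        rate[9, 9] = 4.0
        assert len(extract_fields(rate, arena)) == 2

    def test_fields_partition_supra_threshold_set(self):
        arena = ArenaConfig()
        rng = np.random.default_rng(12)
        for _ in range(100):
            rate = rng.uniform(0, 5, (10, 10))
            fields = extract_fields(rate, arena, 0.2)
            supra = {(i, j) for i, j in zip(*np.nonzero(rate >= 0.2 * rate.max()))}
            pooled = [b for f in fields for b in f.bins]
            assert len(pooled) == len(set(pooled))  # disjoint
            assert set(pooled) == supra
            assert sum(f.size_cm2 for f in fields) == pytest.approx(len(supra) * 16.0)

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            extract_fields(np.zeros((10, 10)), ArenaConfig())


class TestCoherence:
    def test_constant_map_rejected(self):
        arena = ArenaConfig()
        bundle = bundle_from_grids(np.full((10, 10), 2.0), np.ones((10, 10)), arena)
        with pytest.raises(ValidationError):
            spatial_coherence(bundle)

    def test_matches_double_loop_neighbor_oracle(self):
        arena = ArenaConfig()
        rng = np.random.default_rng(13)
        occ = rng.uniform(0, 2, (10, 10))
        occ[rng.random((10, 10)) < 0.3] = 0.0
        counts = rng.poisson(2, (10, 10)) * (occ > 0)
        bundle = bundle_from_grids(counts.astype(float), occ, arena)
        rate = bundle.raw_rate
        visited = occ > 0
        a_vals, b_vals = [], []
        for i in range(10):
            for j in range(10):
                if not visited[i, j]:
                    continue
                neigh = [
                    rate[i + di, j + dj]
                    for di in (-1, 0, 1)
                    for dj in (-1, 0, 1)
                    if (di, dj) != (0, 0)
                    and 0 <= i + di < 10
                    and 0 <= j + dj < 10
                    and visited[i + di, j + dj]
                ]
                if neigh:
                    a_vals.append(rate[i, j])
                    b_vals.append(np.mean(neigh))
        expected = np.arctanh(np.clip(np.corrcoef(a_vals, b_vals)[0, 1], -1 + 1e-12, 1 - 1e-12))
        assert spatial_coherence(bundle) == pytest.approx(expected, abs=1e-12)

    def test_smoothing_increases_coherence(self):
        arena = ArenaConfig()
        rng = np.random.default_rng(14)
        wins = 0
        for trial in range(20):
            occ = np.full((10, 10), 1.0)
            counts = rng.poisson(2, (10, 10)).astype(float)
            raw = bundle_from_grids(counts, occ, arena)
            smooth_rate_map(raw)
            smoothed_as_raw = bundle_from_grids(raw.smoothed_rate * occ, occ, arena)
            if spatial_coherence(smoothed_as_raw) > spatial_coherence(raw):
                wins += 1
        assert wins >= 19


class TestObjectScore:
    def test_center_object_masks_25_bins(self):
        arena = ArenaConfig(object_positions=((20.0, 20.0),))
        assert object_mask(arena).sum() == 25

    def test_corner_object_clipped_to_9(self):
        arena = ArenaConfig(object_positions=((1.0, 1.0),))
        assert object_mask(arena).sum() == 9

    def test_no_objects_empty_mask(self):
        assert object_mask(ArenaConfig()).sum() == 0

    def test_field_inside_mask_scores_one(self):
        arena = ArenaConfig(object_positions=((20.0, 20.0),))
        mask = object_mask(arena)
        rate = np.zeros((10, 10))
        rate[5, 5] = 3.0
        fields = extract_fields(rate, arena)
        assert object_score(fields, mask) == 1.0

    def test_field_disjoint_scores_zero(self):
        arena = ArenaConfig(object_positions=((38.0, 38.0),))
        mask = object_mask(arena)
        rate = np.zeros((10, 10))
        rate[0, 0] = 3.0
        assert object_score(extract_fields(rate, arena), mask) == 0.0

    def test_half_overlap(self):
        arena = ArenaConfig(object_positions=((20.0, 20.0),))
        mask = object_mask(arena)  # columns 3..7, rows 3..7
        rate = np.zeros((10, 10))
        for b in [(7, 6), (7, 7), (8, 6), (8, 7)]:  # (7,*) in, (8,*) out
            rate[b] = 3.0
        fields = extract_fields(rate, arena)
        assert object_score(fields, mask) == pytest.approx(0.5)
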