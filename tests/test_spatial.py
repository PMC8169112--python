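"""Steepest-ascent clustering, peak size and shuffle-null normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from azcalcium import (
    IntensityMap,
    PeakSizeParams,
    average_cluster_size,
    normalized_cluster_size,
    normalized_peak_size,
    null_average_cluster_size,
    peak_size,
    shuffle_map,
    steepest_ascent_clustering,
)
from conftest import make_map
from oracles import (
    brute_force_average_cluster_size,
    brute_force_partition,
    partition_from_labeling,
)


class TestSteepestAscentClustering:
    def test_single_basin_row(self):
        lab = steepest_ascent_clustering(make_map([[1.0, 3.0, 2.0]]))
        assert lab.n_clusters == 1
        assert lab.sizes.tolist() == [3]
        assert lab.peaks.tolist() == [[0, 1]]

    def test_valley_with_neighbor_tie_breaks_to_scan_order(self):
        # middle pixel's neighbors tie at 2; first of (left, right) wins
        lab = steepest_ascent_clustering(make_map([[2.0, 1.0, 2.0]]))
        assert sorted(lab.sizes.tolist()) == [1, 2]
        assert average_cluster_size(lab) == 1.5
        # the middle pixel must join the LEFT peak (first in scan order)
        assert lab.label_map[0, 1] == lab.label_map[0, 0]

    def test_vertical_tie_prefers_up_over_down(self):
        lab = steepest_ascent_clustering(make_map([[5.0], [1.0], [5.0]]))
        assert lab.label_map[1, 0] == lab.label_map[0, 0]

    def test_constant_map_every_pixel_is_a_peak(self):
        lab = steepest_ascent_clustering(make_map(np.ones((3, 4))))
        assert lab.n_clusters == 12
        assert average_cluster_size(lab) == 1.0

    def test_background_pixels_do_not_participate(self):
        # high-valued background pixel must not attract its neighbors
        values = [[1.0, 9.0, 1.0]]
        background = np.array([[False, True, False]])
        lab = steepest_ascent_clustering(make_map(values, background))
        assert lab.n_clusters == 2
        assert lab.label_map[0, 1] == -1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            steepest_ascent_clustering(
                make_map([[1.0]], background=[[True]])
            )

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(30):
            values = rng.permutation(64).reshape(8, 8).astype(float)
            background = rng.random((8, 8)) < 0.2
            if background.all():
                continue
            imap = make_map(values, background)
            lab = steepest_ascent_clustering(imap)
            assert partition_from_labeling(lab.label_map) == brute_force_partition(
                values, background
            )

    @given(st.integers(0, 10_000))
    def test_partition_and_peak_invariants(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(2, 9, size=2)
        values = rng.normal(size=(h, w))
        background = rng.random((h, w)) < 0.25
        if background.all():
            background[0, 0] = False
        imap = make_map(values, background)
        lab = steepest_ascent_clustering(imap)
        assert lab.sizes.sum() == (~background).sum()
        assert len(lab.peaks) == lab.n_clusters
        for label, (r, c) in enumerate(lab.peaks):
            assert lab.label_map[r, c] == label  # peak belongs to its cluster
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not background[rr, cc]:
                    assert values[rr, cc] <= values[r, c]  # no strictly larger neighbor

    def test_rank_invariance_under_monotone_transform(self, rng):
        values = rng.normal(size=(12, 12))
        imap = make_map(values)
        lab1 = steepest_ascent_clustering(imap)
        lab2 = steepest_ascent_clustering(make_map(np.exp(values)))
        assert np.array_equal(lab1.label_map, lab2.label_map)


class TestAverageClusterSize:
    def test_arithmetic(self):
        lab = steepest_ascent_clustering(make_map([[2.0, 1.0, 2.0]]))
        assert average_cluster_size(lab) == pytest.approx(1.5)

    def test_single_cluster_returns_pixel_count(self):
        lab = steepest_ascent_clustering(make_map([[1.0, 2.0, 3.0, 4.0]]))
        assert average_cluster_size(lab) == 4.0


class TestShuffleMap:
    def test_preserves_values_and_mask(self, rng):
        values = rng.normal(size=(6, 6))
        background = rng.random((6, 6)) < 0.3
        imap = make_map(values, background)
        shuffled = shuffle_map(imap, rng)
        assert np.array_equal(shuffled.background_mask, imap.background_mask)
        assert np.allclose(np.sort(shuffled.values()), np.sort(imap.values()))

    def test_fixed_seed_reproducible(self):
        imap = make_map(np.arange(16.0).reshape(4, 4))
        a = shuffle_map(imap, np.random.default_rng(7))
        b = shuffle_map(imap, np.random.default_rng(7))
        assert np.array_equal(a.grid, b.grid)


class TestNullAverageClusterSize:
    def test_constant_map_null_is_one(self):
        imap = make_map(np.ones((5, 5)))
        assert null_average_cluster_size(imap, n_shuffles=5) == 1.0

    def test_matches_brute_force_permutation_oracle_on_4x4(self):
        # Null mean = expected avg cluster size over uniform permutations;
        # estimate it independently with the brute-force path follower.
        values = np.arange(16.0).reshape(4, 4)
        background = np.zeros((4, 4), bool)
        oracle_rng = np.random.default_rng(999)
        oracle_draws = []
        flat = values.ravel().copy()
        for _ in range(3000):
            perm = oracle_rng.permutation(flat).reshape(4, 4)
            oracle_draws.append(brute_force_average_cluster_size(perm, background))
        oracle_mean = np.mean(oracle_draws)
        se = np.std(oracle_draws) / np.sqrt(len(oracle_draws))

        est = null_average_cluster_size(
            make_map(values), n_shuffles=3000, rng=np.random.default_rng(4)
        )
        assert abs(est - oracle_mean) < 6 * se

    def test_requires_at_least_one_shuffle(self):
        with pytest.raises(ValueError):
            null_average_cluster_size(make_map(np.ones((3, 3))), n_shuffles=0)


class TestNormalizedClusterSize:
    def test_phase_frame_count_enforced(self, rng):
        maps = [make_map(rng.normal(size=(6, 6))) for _ in range(4)]
        with pytest.raises(ValueError, match="9 frames"):
            normalized_cluster_size(maps, phase="baseline", n_shuffles=5)
        with pytest.raises(ValueError, match="3 frames"):
            normalized_cluster_size(maps, phase="stimulation", n_shuffles=5)
        res = normalized_cluster_size(maps[:3], phase="stimulation", n_shuffles=5,
                                      rng=rng)
        assert res.frames_used == 3

    def test_structure_free_frames_normalize_to_one(self, rng):
        base = rng.normal(size=(24, 24))
        frames = [shuffle_map(make_map(base), rng) for _ in range(5)]
        res = normalized_cluster_size(frames, n_shuffles=60, rng=rng)
        assert 0.85 < res.normalized < 1.15
        assert res.normalized == pytest.approx(res.observed / res.null_mean)

    def test_invariant_to_additive_intensity_shift(self, rng):
        values = rng.normal(size=(16, 16))
        r1 = normalized_cluster_size([make_map(values)], n_shuffles=30,
                                     rng=np.random.default_rng(3))
        r2 = normalized_cluster_size([make_map(values + 7.5)], n_shuffles=30,
                                     rng=np.random.default_rng(3))
        assert r1.normalized == pytest.approx(r2.normalized, rel=1e-12)


def _map_with_fixed_components():
    """20x16 map (320 px, 5% = 16) whose top-5% pixels form 4-connected
    components of sizes 4, 4 and 8."""
    rng = np.random.default_rng(0)
    values = rng.uniform(0.0, 1.0, size=(20, 16))
    high = np.zeros((20, 16), bool)
    high[1:3, 1:3] = True      # 2x2 -> size 4
    high[1:3, 8:10] = True     # 2x2 -> size 4
    high[10:12, 4:8] = True    # 2x4 -> size 8
    values[high] = 10.0 + rng.uniform(0, 1, size=int(high.sum()))
    return make_map(values), high


class TestPeakSize:
    def test_constructed_components_4_4_8(self):
        imap, high = _map_with_fixed_components()
        assert int(high.sum()) == 16
        assert peak_size(imap) == pytest.approx(16.0 / 3.0)

    def test_isolated_super_threshold_pixels(self):
        values = np.zeros((10, 10))
        values[1, 1] = values[4, 7] = values[8, 3] = 5.0  # 3 isolated of top 5
        values[6, 1] = values[2, 5] = 5.0
        assert peak_size(make_map(values)) == 1.0

    def test_single_solid_block(self):
        values = np.zeros((10, 10))
        values[3, 3:8] = 1.0  # one 5-pixel block above the 95th pct of 100
        assert peak_size(make_map(values)) == pytest.approx(5.0)

    def test_constant_map_has_no_super_threshold_pixels(self):
        with pytest.raises(ValueError, match="percentile"):
            peak_size(make_map(np.ones((8, 8))))

    def test_diagonal_adjacency_does_not_connect(self):
        values = np.zeros((10, 10))
        values[2, 2] = values[3, 3] = values[4, 4] = 9.0
        assert peak_size(make_map(values)) == 1.0

    def test_super_threshold_set_rank_invariant(self, rng):
        values = rng.normal(size=(15, 15))
        p1 = peak_size(make_map(values))
        p2 = peak_size(make_map(np.exp(values)))
        assert p1 == p2

    def test_percentile_bounds_validated(self):
        with pytest.raises(ValueError):
            PeakSizeParams(percentile=100.0)


class TestNormalizedPeakSize:
    def test_structure_free_input_near_one(self, rng):
        imap = make_map(rng.normal(size=(32, 32)))
        res = normalized_peak_size(imap, n_shuffles=100, rng=rng)
        assert 0.8 < res.normalized < 1.2

    def test_clustered_high_pixels_exceed_null(self):
        imap, _ = _map_with_fixed_components()
        res = normalized_peak_size(imap, n_shuffles=100,
                                   rng=np.random.default_rng(1))
        assert res.normalized > 1.5

    def test_fixed_seed_reproducible(self, rng):
        imap = make_map(rng.normal(size=(16, 16)))
        r1 = normalized_peak_size(imap, n_shuffles=50, seed=11)
        r2 = normalized_peak_size(imap, n_shuffles=50, seed=11)
        assert r1.normalized == r2.normalized
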