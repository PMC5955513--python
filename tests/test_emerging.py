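"""Mann-Kendall trend test, space-time Gi*, and 17-way trend labels."""

import itertools

import numpy as np
import pytest

from hotcube.cube import SpaceTimeCube
from hotcube.emerging import (category_vocabulary, classify_emerging,
                              mann_kendall, st_gi_star)
from hotcube.gistar import build_weights, gi_star
from hotcube.grid import CellCounts, GridSpec

from conftest import brute_mann_kendall_s, naive_gi_star, st_neighbor_fn


def _grid(nr, nc, cell=100.0):
    return GridSpec(x_min=0, y_min=0, cell_size=cell, n_cols=nc, n_rows=nr)


def _cube(counts, cell=100.0, mode="calendar_month"):
    counts = np.asarray(counts)
    nr, nc, nt = counts.shape
    return SpaceTimeCube(grid=_grid(nr, nc, cell), mode=mode,
                         bins=tuple(range(nt)), counts=counts)


class TestMannKendall:
    def test_strictly_increasing_series(self):
        res = mann_kendall([1, 2, 3, 4, 5])
        assert res.s == 10
        assert res.direction == "up"

    def test_constant_series_has_no_trend(self):
        res = mann_kendall([4, 4, 4, 4])
        assert res.s == 0
        assert res.direction == "none"

    def test_mixed_series_matches_pairwise_count(self):
        res = mann_kendall([3, 1, 2, 5, 4])
        assert res.s == 4
        assert res.s == brute_mann_kendall_s([3, 1, 2, 5, 4])

    def test_reversal_negates_s_exactly(self, rng):
        for _ in range(20):
            a = rng.integers(0, 6, size=int(rng.integers(3, 12)))
            assert mann_kendall(a[::-1]).s == -mann_kendall(a).s

    def test_s_matches_brute_force_on_short_series(self, rng):
        # fixed enumeration of random integer series of lengths 3..7
        for _ in range(100):
            n = int(rng.integers(3, 8))
            a = rng.integers(0, 5, size=n)
            assert mann_kendall(a).s == brute_mann_kendall_s(a)

    def test_tie_corrected_variance(self):
        # n=5, one tie group of size 2: var = [5*4*15 - 2*1*9]/18
        res = mann_kendall([1, 2, 2, 3, 4])
        assert res.var_s == pytest.approx((300 - 18) / 18)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            mann_kendall([1, 2])

    def test_sign_consistency_and_p_range(self, rng):
        for _ in range(20):
            a = rng.normal(size=8)
            res = mann_kendall(a)
            if res.s != 0:
                assert np.sign(res.z) == np.sign(res.s)
            assert 0.0 <= res.p <= 1.0


class TestCategoryVocabulary:
    def test_exactly_17_labels(self):
        assert len(category_vocabulary()) == 17

    def test_contains_expected_members(self):
        vocab = category_vocabulary()
        assert "sporadic hotspot" in vocab
        assert "no pattern" in vocab
        assert "oscillating coldspot" in vocab


class TestStGiStar:
    def test_lag0_single_bin_reduces_to_plain_gi_star(self, rng):
        counts = rng.poisson(3.0, (4, 4, 1))
        cube = _cube(counts)
        w = build_weights(cube.grid, 150.0)
        zt = st_gi_star(cube, w, time_lag=0)
        plain = gi_star(CellCounts(grid=cube.grid, counts=counts[:, :, 0]), w)
        np.testing.assert_allclose(zt[:, :, 0], plain.z, atol=1e-12)

    def test_4x4x6_cube_matches_naive_space_time_oracle(self, rng):
        counts = rng.poisson(2.0, (4, 4, 6)).astype(float)
        cube = _cube(counts)
        w = build_weights(cube.grid, 150.0)
        zt = st_gi_star(cube, w, time_lag=1)
        nfn = st_neighbor_fn(counts.shape, 100.0, 150.0, time_lag=1)
        oracle = naive_gi_star(counts, nfn)
        assert np.abs(zt - oracle).max() < 1e-12

    def test_degenerate_cube_gives_zero_tensor(self):
        cube = _cube(np.full((3, 3, 4), 5))
        zt = st_gi_star(cube, build_weights(cube.grid, 150.0))
        assert not zt.any()

    def test_planted_burst_elevates_z_only_in_active_bins(self, rng):
        counts = rng.poisson(1.0, (7, 7, 8)).astype(int)
        counts[3, 3, 4:7] += 25
        cube = _cube(counts)
        zt = st_gi_star(cube, build_weights(cube.grid, 150.0), time_lag=1)
        assert zt[3, 3, 4:7].min() > zt[3, 3, 0:3].max()
        # bins whose past-lag window lies fully inside the burst are extreme
        assert zt[3, 3, 5:7].min() > 2.58


class TestClassifyEmerging:
    """Constructed significance histories map to their rule-table labels."""

    def _field_for(self, z_series, counts_series):
        nt = len(z_series)
        z = np.zeros((1, 2, nt))
        z[0, 0, :] = z_series
        counts = np.ones((1, 2, nt), dtype=int)
        counts[0, 0, :] = counts_series
        cube = _cube(counts)
        return classify_emerging(z, cube).labels[0, 0]

    def test_significant_only_in_final_bin_is_new(self):
        z = [0.0] * 9 + [2.0]
        assert self._field_for(z, [1] * 10) == "new hotspot"

    def test_unbroken_final_run_is_consecutive(self):
        z = [0.0] * 6 + [2.0] * 4
        assert self._field_for(z, [1] * 10) == "consecutive hotspot"

    def test_always_hot_flat_counts_is_persistent(self):
        assert self._field_for([2.0] * 10, [5] * 10) == "persistent hotspot"

    def test_always_hot_rising_counts_is_intensifying(self):
        assert self._field_for([2.0] * 10, list(range(1, 11))) \
            == "intensifying hotspot"

    def test_always_hot_falling_counts_is_diminishing(self):
        assert self._field_for([2.0] * 10, list(range(10, 0, -1))) \
            == "diminishing hotspot"

    def test_interrupted_history_is_sporadic(self):
        z = [2.0, 0.0, 2.0, 0.0, 0.0, 2.0, 0.0, 2.0, 0.0, 2.0]
        assert self._field_for(z, [1] * 10) == "sporadic hotspot"

    def test_opposite_sign_history_is_oscillating(self):
        z = [-2.0, -2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 2.0]
        assert self._field_for(z, [1] * 10) == "oscillating hotspot"

    def test_hot_history_quiet_finale_is_historical(self):
        z = [2.0] * 9 + [0.0]
        assert self._field_for(z, [1] * 10) == "historical hotspot"

    def test_cold_mirror_labels(self):
        z = [0.0] * 9 + [-2.0]
        assert self._field_for(z, [1] * 10) == "new coldspot"
        z = [-2.0] * 10
        assert self._field_for(z, [5] * 10) == "persistent coldspot"
        # intensifying coldspot: cold throughout with counts falling
        assert self._field_for([-2.0] * 10, list(range(10, 0, -1))) \
            == "intensifying coldspot"

    def test_all_zero_cube_is_all_no_pattern(self):
        cube = _cube(np.zeros((3, 3, 12), int))
        z = np.zeros((3, 3, 12))
        labels = classify_emerging(z, cube).labels
        assert (labels == "no pattern").all()

    def test_invariant_under_count_scaling(self, rng):
        counts = rng.poisson(3.0, (3, 3, 10))
        cube = _cube(counts)
        z = rng.normal(0, 2, (3, 3, 10))
        l1 = classify_emerging(z, cube).labels
        l2 = classify_emerging(z, _cube(counts * 7)).labels
        np.testing.assert_array_equal(l1, l2)

    def test_every_cell_gets_exactly_one_valid_label(self, rng):
        counts = rng.poisson(2.0, (4, 5, 12))
        z = rng.normal(0, 2, (4, 5, 12))
        labels = classify_emerging(z, _cube(counts)).labels
        vocab = set(category_vocabulary())
        assert labels.shape == (4, 5)
        assert all(l in vocab for l in labels.ravel())

    def test_shape_mismatch_raises(self):
        cube = _cube(np.zeros((2, 2, 12), int))
        with pytest.raises(ValueError, match="shape"):
            classify_emerging(np.zeros((2, 2, 6)), cube)
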