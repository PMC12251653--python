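"""Sample selection, outlier screening, and scatter corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specshift.preprocess import (
    kennard_stone_split,
    loo_pls_outlier_screen,
    msc,
    random_split,
    snv,
    spxy_split,
    train_size,
    truncate_wavelengths,
)


def brute_force_maxmin(D: np.ndarray, n_train: int) -> list[int]:
    """Independent re-implementation of sequential max-min selection."""
    n = D.shape[0]
    best, pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best:
                best, pair = D[i, j], (i, j)
    sel = list(pair)
    while len(sel) < n_train:
        cand_best, cand = -1.0, None
        for i in range(n):
            if i in sel:
                continue
            d = min(D[i, j] for j in sel)
            if d > cand_best:
                cand_best, cand = d, i
        sel.append(cand)
    return sel


class TestKennardStone:
    def test_one_dimensional_extremes(self):
        X = np.array([[0.0], [1.0], [10.0]])
        res = kennard_stone_split(X, 2 / 3)
        assert sorted(res.train_indices) == [0, 2]
        assert res.test_indices == [1]

    def test_collinear_points_pick_endpoints(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        res = kennard_stone_split(X, 0.5)
        assert sorted(res.train_indices) == [0, 3]

    def test_identical_points_tie_break_low_index(self):
        X = np.zeros((5, 3))
        res = kennard_stone_split(X, 0.6)
        assert res.train_indices == [0, 1, 2]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 11)
            X = rng.random((n, 4))
            n_train = int(rng.integers(2, n + 1))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            expected = brute_force_maxmin(D, n_train)
            got = kennard_stone_split(X, n_train / n).train_indices
            assert got == expected

    def test_split_sizes_follow_half_up_rounding(self):
        assert train_size(80, 0.8) == 64
        assert train_size(636, 0.8) == 509
        X = np.random.default_rng(1).random((80, 6))
        res = kennard_stone_split(X, 0.8)
        assert len(res.train_indices) == 64
        assert len(res.test_indices) == 16

    def test_too_small_fraction_rejected(self):
        X = np.random.default_rng(2).random((10, 3))
        with pytest.raises(ValueError, match="train"):
            kennard_stone_split(X, 0.05)


class TestSPXY:
    def test_constant_y_reduces_to_kennard_stone(self):
        rng = np.random.default_rng(3)
        X = rng.random((12, 5))
        ks = kennard_stone_split(X, 0.5)
        sp = spxy_split(X, np.ones(12), 0.5)
        assert sp.train_indices == ks.train_indices

    def test_constant_x_selects_on_y(self):
        X = np.ones((3, 4))
        Y = np.array([0.0, 1.0, 10.0])
        res = spxy_split(X, Y, 2 / 3)
        assert sorted(res.train_indices) == [0, 2]

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X, Y = rng.random((15, 6)), rng.random(15)
        a = spxy_split(X, Y, 0.8)
        b = spxy_split(X, Y, 0.8)
        assert a.train_indices == b.train_indices

    def test_fully_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            spxy_split(np.ones((4, 3)), np.ones(4), 0.5)


class TestPermutationCovariance:
    def test_ks_covariant_under_sample_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.random((10, 4))
        perm = rng.permutation(10)
        base = kennard_stone_split(X, 0.6)
        permuted = kennard_stone_split(X[perm], 0.6)
        mapped = sorted(perm[permuted.train_indices].tolist())
        assert mapped == sorted(base.train_indices)


class TestOutlierScreen:
    @staticmethod
    def _linear_data(n=30, p=20, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, p))
        w = rng.random(p)
        return X, X @ w

    def test_clean_linear_data_keeps_everything(self):
        X, y = self._linear_data()
        rep = loo_pls_outlier_screen(X, y, n_components=5, threshold=30.0)
        assert rep.removed_indices == []

    def test_single_corrupted_sample_flagged(self):
        # a +10 sd shift on one reference value: large enough that its own
        # held-out squared error far exceeds the cutoff, small enough that
        # the models fitted with it stay accurate at every other sample
        X, y = self._linear_data()
        y = y.copy()
        y[13] += 10.0 * y.std()
        rep = loo_pls_outlier_screen(X, y, n_components=5, threshold=30.0)
        assert rep.removed_indices == [13]

    def test_infinite_threshold_removes_nothing(self):
        X, y = self._linear_data(seed=1)
        y[4] += 1e3
        rep = loo_pls_outlier_screen(X, y, n_components=5, threshold=np.inf)
        assert rep.removed_indices == []

    def test_threshold_monotonicity(self):
        X, y = self._linear_data(seed=2)
        y = y + np.random.default_rng(2).normal(0, 0.5, y.size)
        counts = []
        for thr in (0.01, 0.1, 1.0, 10.0):
            rep = loo_pls_outlier_screen(X, y, n_components=5, threshold=thr)
            counts.append(len(rep.removed_indices))
        assert counts == sorted(counts, reverse=True)

    def test_nonpositive_threshold_rejected(self):
        X, y = self._linear_data()
        with pytest.raises(ValueError, match="threshold"):
            loo_pls_outlier_screen(X, y, threshold=0.0)


class TestTruncation:
    def test_keeps_first_n_columns(self, master_set):
        out = truncate_wavelengths(master_set, 53)
        assert out.X.shape[1] == 53
        np.testing.assert_array_equal(out.wavelengths, master_set.wavelengths[:53])
        np.testing.assert_array_equal(out.X, master_set.X[:, :53])

    def test_full_length_is_identity(self, master_set):
        out = truncate_wavelengths(master_set, master_set.n_wavelengths)
        assert out.equals(master_set) or out.X.shape == master_set.X.shape

    def test_single_column_still_valid(self, master_set):
        out = truncate_wavelengths(master_set, 1)
        assert out.n_wavelengths == 1
        out.validate()

    @pytest.mark.parametrize("bad", [0, 121, -3])
    def test_out_of_range_rejected(self, master_set, bad):
        with pytest.raises(ValueError):
            truncate_wavelengths(master_set, bad)


class TestScatterCorrections:
    def test_snv_hand_case(self):
        out = snv(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])

    def test_snv_idempotent(self):
        X = np.random.default_rng(6).random((5, 30))
        once = snv(X)
        np.testing.assert_allclose(snv(once), once, atol=1e-12)

    def test_snv_zero_variance_row_named(self):
        X = np.vstack([np.random.default_rng(7).random(10), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="1"):
            snv(X)

    def test_msc_recovers_reference_under_exact_affine_model(self):
        rng = np.random.default_rng(8)
        ref = rng.random(40)
        slopes = rng.uniform(0.5, 2.0, 6)
        intercepts = rng.uniform(-1, 1, 6)
        X = slopes[:, None] * ref + intercepts[:, None]
        out = msc(X, reference=ref)
        np.testing.assert_allclose(out, np.tile(ref, (6, 1)), atol=1e-10)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_snv_rows_have_zero_mean_unit_sd(self, seed):
        X = np.random.default_rng(seed).random((4, 12)) + 0.01 * np.arange(12)
        out = snv(X)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-10)


class TestRandomSplit:
    def test_seeded_and_partitioning(self):
        X = np.random.default_rng(9).random((20, 3))
        a = random_split(X, 0.8, seed=5)
        b = random_split(X, 0.8, seed=5)
        assert a.train_indices == b.train_indices
        assert sorted(a.train_indices + a.test_indices) == list(range(20))
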