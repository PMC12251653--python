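"""PLS/SVR regressors and the classical calibration-transfer trio."""

import numpy as np
import pytest

from specshift.baselines import (
    AffineCorrection,
    ds_apply,
    ds_fit,
    pds_fit,
    pls_fit,
    pls_predict,
    sbc_apply,
    sbc_fit,
    svr_fit,
)
from specshift.metrics import evaluate


@pytest.fixture(scope="module")
def linear_problem():
    # rank-5 spectra (5 latent constituents) with y exactly linear in X, so
    # a 5-component PLS model can recover the relation exactly
    rng = np.random.default_rng(0)
    scores = rng.random((40, 5))
    loadings = rng.random((5, 30))
    X = scores @ loadings
    w = rng.random(30)
    return X, X @ w


class TestPLS:
    def test_exact_recovery_at_full_effective_rank(self, linear_problem):
        X, y = linear_problem
        model = pls_fit(X, y, n_components=5)
        rep = evaluate(y, pls_predict(model, X))
        assert rep.r2 >= 0.999

    def test_predictions_finite(self, linear_problem):
        X, y = linear_problem
        model = pls_fit(X, y, 5)
        assert np.all(np.isfinite(pls_predict(model, X)))

    def test_deterministic_coefficients(self, linear_problem):
        X, y = linear_problem
        a = pls_fit(X, y, 5)
        b = pls_fit(X, y, 5)
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pls_fit(np.ones((10, 5)), np.arange(10.0), 2)


class TestSVR:
    def test_linear_data_fit(self):
        rng = np.random.default_rng(1)
        X = rng.random((60, 10))
        y = 3.0 * X[:, 4]
        model = svr_fit(X, y, C=10.0, epsilon=0.001)
        rep = evaluate(y, model.predict(X))
        assert rep.r2 >= 0.99

    def test_duplicate_rows_do_not_change_predictions(self):
        # in the constraint-dominated regime (large C, noiseless data) the
        # solution is the min-norm hyperplane fitting every point within the
        # epsilon tube, which is invariant under duplicating the sample set
        rng = np.random.default_rng(2)
        X = rng.random((20, 5))
        y = X @ rng.random(5)
        m1 = svr_fit(X, y, C=1e6, epsilon=0.05)
        m2 = svr_fit(np.vstack([X, X]), np.concatenate([y, y]), C=1e6, epsilon=0.05)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X), atol=1e-6)

    def test_predictions_affine_in_inputs(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 4))
        y = X @ rng.random(4) + 1.0
        model = svr_fit(X, y)
        a, b = rng.random((2, 4))
        lhs = model.predict((a + b)[None, :] / 2)
        rhs = (model.predict(a[None, :]) + model.predict(b[None, :])) / 2
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_gamma_warning_logged(self, caplog):
        rng = np.random.default_rng(4)
        X, y = rng.random((10, 3)), rng.random(10)
        with caplog.at_level("WARNING"):
            svr_fit(X, y, gamma=0.001)
        assert any("gamma" in r.message for r in caplog.records)


class TestDirectStandardization:
    def test_identity_when_slave_equals_master(self):
        rng = np.random.default_rng(5)
        M = rng.random((20, 8))
        smap = ds_fit(M, M, ridge=1e-12)
        np.testing.assert_allclose(ds_apply(smap, M), M, atol=1e-8)

    def test_recovers_invertible_linear_map(self):
        rng = np.random.default_rng(6)
        p = 12
        master = rng.random((30, p))  # more standards than wavelengths
        T = np.eye(p) + 0.3 * rng.random((p, p))
        slave = master @ T
        smap = ds_fit(master, slave, ridge=0.0)
        corrected = ds_apply(smap, slave)
        assert np.abs(corrected - master).max() <= 1e-6

    def test_huge_ridge_shrinks_map_to_zero(self):
        rng = np.random.default_rng(7)
        M, S = rng.random((10, 6)), rng.random((10, 6))
        smap = ds_fit(M, S, ridge=1e12)
        assert np.abs(smap.F).max() < 1e-6

    def test_linearity_of_correction(self):
        rng = np.random.default_rng(8)
        M, S = rng.random((15, 7)), rng.random((15, 7))
        smap = ds_fit(M, S)
        X1, X2 = rng.random((4, 7)), rng.random((4, 7))
        lhs = ds_apply(smap, 2.0 * X1 + 3.0 * X2)
        rhs = 2.0 * ds_apply(smap, X1) + 3.0 * ds_apply(smap, X2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            ds_fit(np.ones((4, 3)), np.ones((5, 3)))


class TestPiecewiseDS:
    def test_window_zero_recovers_per_column_scale(self):
        rng = np.random.default_rng(9)
        master = rng.random((12, 6))
        slave = 2.5 * master
        smap = pds_fit(master, slave, window=0, ridge=0.0)
        np.testing.assert_allclose(np.diag(smap.F), 1 / 2.5, atol=1e-10)
        np.testing.assert_allclose(ds_apply(smap, slave), master, atol=1e-8)

    def test_band_structure(self):
        rng = np.random.default_rng(10)
        M, S = rng.random((15, 10)), rng.random((15, 10))
        w = 2
        smap = pds_fit(M, S, window=w)
        i, j = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        assert np.all(smap.F[np.abs(i - j) > w] == 0)

    def test_full_window_matches_ds(self):
        rng = np.random.default_rng(11)
        master = rng.random((25, 10))
        slave = master @ (np.eye(10) + 0.2 * rng.random((10, 10)))
        ds_map = ds_fit(master, slave, ridge=1e-8)
        pds_map = pds_fit(master, slave, window=9, ridge=1e-8)
        assert np.abs(ds_map.F - pds_map.F).max() <= 1e-6

    def test_identity_when_equal(self):
        rng = np.random.default_rng(12)
        M = rng.random((20, 8))
        smap = pds_fit(M, M, window=3, ridge=1e-12)
        np.testing.assert_allclose(ds_apply(smap, M), M, atol=1e-8)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            pds_fit(np.ones((5, 4)), np.ones((5, 4)), window=4)


class TestSlopeBiasCorrection:
    def test_inverts_constructed_affine_bias(self):
        rng = np.random.default_rng(13)
        y_ref = rng.random(20) * 10
        yhat = (y_ref - 1.0) / 2.0
        corr = sbc_fit(y_ref, yhat)
        assert corr.slope == pytest.approx(2.0, abs=1e-9)
        assert corr.bias == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(sbc_apply(corr, yhat), y_ref, atol=1e-9)

    def test_identity_predictions(self):
        y = np.random.default_rng(14).random(10)
        corr = sbc_fit(y, y)
        assert corr.slope == pytest.approx(1.0)
        assert corr.bias == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_residual_on_standards(self):
        rng = np.random.default_rng(15)
        y = rng.random(25)
        yhat = y + rng.normal(0, 0.1, 25)
        corr = sbc_fit(y, yhat)
        resid = y - sbc_apply(corr, yhat)
        assert resid.mean() == pytest.approx(0.0, abs=1e-12)

    def test_never_degrades_in_standard_mse(self):
        rng = np.random.default_rng(16)
        y = rng.random(30)
        yhat = 1.7 * y - 0.4 + rng.normal(0, 0.05, 30)
        corr = sbc_fit(y, yhat)
        mse_before = np.mean((y - yhat) ** 2)
        mse_after = np.mean((y - sbc_apply(corr, yhat)) ** 2)
        assert mse_after <= mse_before + 1e-15

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sbc_fit(np.arange(5.0), np.ones(5))

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            AffineCorrection(slope=0.0, bias=1.0)
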