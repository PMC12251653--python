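"""Comparison methods: PLS, linear SVR, a plain-convolution network, and the
classical calibration-transfer trio (DS, PDS, SBC).

Direct standardization (DS) estimates a full wavelengths-by-wavelengths
linear map from slave spectra to master spectra on transfer standards —
samples measured on both instruments.  Piecewise direct standardization (PDS)
restricts the map to a moving window around each wavelength, giving a banded
matrix.  Slope-and-bias correction (SBC) leaves spectra alone and corrects
the master model's *predictions* on the slave by ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR

from .model import ModelConfig, NetworkHandle

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationMap",
    "AffineCorrection",
    "pls_fit",
    "pls_predict",
    "svr_fit",
    "plain_cnn",
    "ds_fit",
    "ds_apply",
    "pds_fit",
    "pds_apply",
    "sbc_fit",
    "sbc_apply",
]


# ----------------------------------------------------------------------
# Regression baselines
# ----------------------------------------------------------------------

def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int = 5) -> PLSRegression:
    """Partial least squares regression (NIPALS, unscaled columns)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("X has zero variance in every column: PLS undefined")
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, np.asarray(y, dtype=float).ravel())
    return model


def pls_predict(model: PLSRegression, X: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(np.atleast_2d(X))).ravel()


def svr_fit(X: np.ndarray, y: np.ndarray, C: float = 1.0, epsilon: float = 0.01,
            gamma: float | None = None) -> SVR:
    """Epsilon-insensitive support vector regression with a linear kernel.

    ``gamma`` is accepted for config fidelity but has no effect on a linear
    kernel; a warning is logged when it is supplied.
    """
    if gamma is not None:
        logger.warning(
            "gamma=%s supplied but the linear kernel ignores it", gamma
        )
    model = SVR(kernel="linear", C=C, epsilon=epsilon)
    model.fit(np.atleast_2d(X), np.asarray(y, dtype=float).ravel())
    return model


def plain_cnn(config: ModelConfig, seed: int = 0) -> NetworkHandle:
    """Ablation network: every RX-Inception block replaced by one standard
    convolution (kernel M1, the block's output width); SE and residual go
    with the block.  Same parameter groups, so all six transfer strategies
    apply unchanged."""
    return NetworkHandle(config, seed, block_factory="plain")


# ----------------------------------------------------------------------
# Classical calibration transfer
# ----------------------------------------------------------------------

@dataclass
class StandardizationMap:
    """Slave-to-master spectral transform: ``corrected = X @ F + intercept``."""

    F: np.ndarray
    intercept: np.ndarray
    window: int | None = None  # PDS half-width; None for DS
    ridge: float = 0.0


@dataclass
class AffineCorrection:
    slope: float
    bias: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


def _check_standards(master_std: np.ndarray, slave_std: np.ndarray):
    M = np.atleast_2d(np.asarray(master_std, dtype=float))
    S = np.atleast_2d(np.asarray(slave_std, dtype=float))
    if M.shape[0] != S.shape[0]:
        raise ValueError(
            f"master and slave standards have different sample counts "
            f"({M.shape[0]} vs {S.shape[0]}); rows must be the same samples"
        )
    return M, S


def ds_fit(master_std: np.ndarray, slave_std: np.ndarray, ridge: float = 1e-6,
           center: bool = False) -> StandardizationMap:
    """Direct standardization: ridge-regularised least squares for F in
    ``master ~ slave @ F``; optional centring adds an intercept row."""
    M, S = _check_standards(master_std, slave_std)
    if center:
        m_mean, s_mean = M.mean(axis=0), S.mean(axis=0)
        M = M - m_mean
        S = S - s_mean
    p = S.shape[1]
    A = S.T @ S + ridge * np.eye(p)
    F = np.linalg.solve(A, S.T @ M)
    intercept = (m_mean - s_mean @ F) if center else np.zeros(M.shape[1])
    return StandardizationMap(F=F, intercept=intercept, window=None, ridge=ridge)


def ds_apply(smap: StandardizationMap, slave_X: np.ndarray) -> np.ndarray:
    return np.atleast_2d(slave_X) @ smap.F + smap.intercept


def pds_fit(master_std: np.ndarray, slave_std: np.ndarray, window: int = 5,
            ridge: float = 1e-6, center: bool = False) -> StandardizationMap:
    """Piecewise direct standardization: per master wavelength j, regress on
    the slave window ``[j-w, j+w]`` (edges truncated); assemble a banded F."""
    M, S = _check_standards(master_std, slave_std)
    p = S.shape[1]
    if window < 0 or window >= p:
        raise ValueError(f"window half-width must be in [0, {p - 1}]")
    if center:
        m_mean, s_mean = M.mean(axis=0), S.mean(axis=0)
        M = M - m_mean
        S = S - s_mean
    F = np.zeros((p, M.shape[1]))
    for j in range(M.shape[1]):
        lo, hi = max(0, j - window), min(p, j + window + 1)
        Sw = S[:, lo:hi]
        A = Sw.T @ Sw + ridge * np.eye(hi - lo)
        F[lo:hi, j] = np.linalg.solve(A, Sw.T @ M[:, j])
    intercept = (m_mean - s_mean @ F) if center else np.zeros(M.shape[1])
    return StandardizationMap(F=F, intercept=intercept, window=window, ridge=ridge)


pds_apply = ds_apply  # identical application rule; F is just banded


def sbc_fit(y_ref: np.ndarray, yhat_slave: np.ndarray) -> AffineCorrection:
    """Slope-and-bias correction: OLS of the reference values on the master
    model's predictions for the slave standards."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    yhat = np.asarray(yhat_slave, dtype=float).ravel()
    if y_ref.size != yhat.size or y_ref.size < 2:
        raise ValueError("need >= 2 standards with matching lengths")
    if np.ptp(yhat) == 0:
        raise ValueError("predictions on standards are constant: SBC undefined")
    slope, bias = np.polyfit(yhat, y_ref, 1)
    return AffineCorrection(slope=float(slope), bias=float(bias))


def sbc_apply(corr: AffineCorrection, yhat: np.ndarray) -> np.ndarray:
    return corr.slope * np.asarray(yhat, dtype=float) + corr.bias
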