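"""Distribution-adaptation losses for calibration transfer.

The marginal term (MDA) is the squared maximum mean discrepancy between
source- and target-domain *features*; the conditional term (CDA) is the same
statistic on the model *outputs*.  The balanced combination

    L_total = L_MSE + lambda1 * L_MDA + lambda1 * lambda2 * L_CDA

is the fine-tuning objective when distribution adaptation is switched on.

The MMD estimator is the biased V-statistic

    mean(K_ss) + mean(K_tt) - 2 * mean(K_st)

of the squared RKHS mean-embedding distance; the squared form is smooth at
zero, which matters because it is optimised by gradient descent.  The default
kernel is an RBF with a median-heuristic bandwidth computed per batch on the
pooled pairwise squared distances; a fixed bandwidth is available for exact
oracle tests.  All losses accept either numpy arrays (returning floats) or
autodiff tensors (returning tensors through which gradients flow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "MMDConfig",
    "LossWeights",
    "mmd2",
    "mda_loss",
    "cda_loss",
    "mse_loss",
    "total_loss",
    "median_bandwidth",
]


@dataclass
class MMDConfig:
    kernel: str = "rbf"
    bandwidth_rule: str = "median"  # "median" or "fixed"
    bandwidth: float = 1.0          # used when bandwidth_rule == "fixed"

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.bandwidth_rule not in ("median", "fixed"):
            raise ValueError("bandwidth_rule must be 'median' or 'fixed'")
        if self.bandwidth_rule == "fixed" and self.bandwidth <= 0:
            raise ValueError("fixed bandwidth must be positive")


@dataclass
class LossWeights:
    """lambda1 weights the whole BDA block; lambda2 the CDA term inside it."""

    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")


def _as_2d_tensor(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
    if t.data.ndim == 1:
        t = t.reshape(t.data.size, 1)
    if t.data.ndim != 2:
        raise ValueError(f"expected a 2-D sample-by-feature array, got ndim={t.data.ndim}")
    return t


def _sq_dists(a: Tensor, b: Tensor) -> Tensor:
    # ||a_i - b_j||^2 = |a_i|^2 + |b_j|^2 - 2 a_i.b_j, floored at 0
    na = (a * a).sum(axis=1, keepdims=True)        # (n, 1)
    nb = (b * b).sum(axis=1, keepdims=True)        # (m, 1)
    d = na + nb.transpose2d() + (a @ b.transpose2d()) * (-2.0)
    return d.relu()  # clip the tiny negatives from cancellation


def median_bandwidth(Xs: np.ndarray, Xt: np.ndarray) -> float:
    """Median-heuristic RBF bandwidth: sigma^2 = median of the pooled nonzero
    pairwise squared distances (falls back to 1.0 if all distances vanish)."""
    Z = np.vstack([np.atleast_2d(Xs), np.atleast_2d(Xt)])
    sq = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
    vals = sq[np.triu_indices(Z.shape[0], k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    return float(np.sqrt(np.median(vals)))


def _kernel_matrix(a: Tensor, b: Tensor, cfg: MMDConfig, sigma: float) -> Tensor:
    if cfg.kernel == "linear":
        return a @ b.transpose2d()
    d = _sq_dists(a, b)
    return (d * (-1.0 / (2.0 * sigma**2))).exp()


def mmd2(Xs, Xt, cfg: MMDConfig | None = None):
    """Squared maximum mean discrepancy between two sample sets.

    Returns a float for array inputs, a differentiable Tensor for tensor
    inputs.  Nonnegative up to numerical tolerance; tiny negative values are
    clipped to zero.
    """
    cfg = cfg or MMDConfig()
    s = _as_2d_tensor(Xs)
    t = _as_2d_tensor(Xt)
    if s.data.shape[1] != t.data.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {s.data.shape[1]} vs {t.data.shape[1]}"
        )
    if cfg.kernel == "rbf" and cfg.bandwidth_rule == "median":
        sigma = median_bandwidth(s.data, t.data)
    else:
        sigma = cfg.bandwidth
    val = (
        _kernel_matrix(s, s, cfg, sigma).mean()
        + _kernel_matrix(t, t, cfg, sigma).mean()
        + _kernel_matrix(s, t, cfg, sigma).mean() * (-2.0)
    )
    if isinstance(Xs, Tensor) or isinstance(Xt, Tensor):
        return val.relu()  # keep the graph; clip at zero
    return max(0.0, float(val.data))


def mda_loss(Xs, Xt, cfg: MMDConfig | None = None):
    """Marginal distribution adaptation: MMD^2 on domain features."""
    return mmd2(Xs, Xt, cfg)


def cda_loss(Ys, Yt, cfg: MMDConfig | None = None):
    """Conditional distribution adaptation: MMD^2 on model outputs."""
    return mmd2(Ys, Yt, cfg)


def mse_loss(y, yhat):
    """Mean squared error; differentiable when inputs are tensors."""
    yt = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=float))
    pt = yhat if isinstance(yhat, Tensor) else Tensor(np.asarray(yhat, dtype=float))
    if yt.data.size != pt.data.size:
        raise ValueError(f"length mismatch: {yt.data.size} vs {pt.data.size}")
    n = yt.data.size
    diff = yt.reshape(n, 1) - pt.reshape(n, 1)
    out = (diff * diff).mean()
    if isinstance(y, Tensor) or isinstance(yhat, Tensor):
        return out
    return float(out.data)


def total_loss(mse, mda, cda, weights: LossWeights):
    """Fine-tuning objective: mse + lambda1*mda + lambda1*lambda2*cda."""
    if weights.lambda1 < 0 or weights.lambda2 < 0:
        raise ValueError("loss weights must be nonnegative")
    for name, v in (("mse", mse), ("mda", mda), ("cda", cda)):
        val = float(v.data) if isinstance(v, Tensor) else float(v)
        if not np.isfinite(val):
            raise ValueError(f"{name} term is not finite")
    return mse + weights.lambda1 * mda + (weights.lambda1 * weights.lambda2) * cda
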