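"""Regression evaluation: R-squared, RMSE, MAE, and before/after deltas.

R-squared is computed about the test-set mean, so a model worse than the
constant mean predictor scores negative — the convention that makes failed
cross-instrument predictions visible (some chemometrics software instead
uses the calibration-set mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "evaluate", "paired_report", "ConstantTargetError"]


class ConstantTargetError(ValueError):
    """R-squared is undefined for a constant reference vector.

    Carries the partial report (RMSE/MAE, r2=None) on ``partial``.
    """

    def __init__(self, message: str, partial: "EvalReport"):
        super().__init__(message)
        self.partial = partial


@dataclass
class EvalReport:
    r2: float | None
    rmse: float
    mae: float
    n: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae, "n": self.n}


def evaluate(y, yhat) -> EvalReport:
    """Compute R-squared, RMSE and MAE of predictions against references."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ValueError(f"need equal nonzero lengths, got {y.size} and {yhat.size}")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise ConstantTargetError(
            "reference values are constant: R2 undefined",
            EvalReport(r2=None, rmse=rmse, mae=mae, n=y.size),
        )
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return EvalReport(r2=r2, rmse=rmse, mae=mae, n=y.size)


def paired_report(before: EvalReport, after: EvalReport) -> dict:
    """Metric deltas (after - before) with per-metric improvement flags."""
    out = {}
    for m in ("r2", "rmse", "mae"):
        b, a = getattr(before, m), getattr(after, m)
        delta = None if b is None or a is None else a - b
        improved = None
        if delta is not None:
            improved = delta > 0 if m == "r2" else delta < 0
        out[m] = {"before": b, "after": a, "delta": delta, "improved": improved}
    return out
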