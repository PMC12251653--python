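"""Generic before/after-transfer prediction plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["prediction_scatter"]


def prediction_scatter(y, yhat_before, yhat_after, path, title: str = "") -> Path:
    """Scatter predicted vs true values before and after transfer.

    Green points: predictions of the untransferred master model; yellow
    points: predictions after transfer; the identity line marks perfect
    prediction.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    lo = min(y.min(), np.min(yhat_after))
    hi = max(y.max(), np.max(yhat_after))
    ax.plot([lo, hi], [lo, hi], color="tab:blue", lw=1, label="true")
    ax.scatter(y, yhat_before, s=18, color="tab:green", alpha=0.7, label="before transfer")
    ax.scatter(y, yhat_after, s=18, color="gold", alpha=0.9, label="after transfer")
    ax.set_xlabel("reference value")
    ax.set_ylabel("predicted value")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
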