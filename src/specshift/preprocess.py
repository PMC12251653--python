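"""Sample selection, outlier screening and scatter-correction transforms.

Kennard–Stone picks calibration samples by sequential max–min Euclidean
distance so that the training set spans the spectral space; SPXY applies the
same rule to a joint spectral+response distance.  The outlier screen fits a
leave-one-out PLS model and flags samples whose held-out squared prediction
error exceeds a threshold (the classical chemometric screen with an MSE
cutoff).  SNV and MSC are the two standard row-wise scatter corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression

from .data import SpectraSet

__all__ = [
    "SplitResult",
    "OutlierReport",
    "kennard_stone_split",
    "spxy_split",
    "random_split",
    "loo_pls_outlier_screen",
    "truncate_wavelengths",
    "snv",
    "msc",
    "train_size",
]


@dataclass
class SplitResult:
    train_indices: list[int]
    test_indices: list[int]
    method: str
    ratio: float

    def __post_init__(self) -> None:
        overlap = set(self.train_indices) & set(self.test_indices)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")


@dataclass
class OutlierReport:
    per_sample_mse: np.ndarray
    removed_indices: list[int]
    threshold: float

    @property
    def kept_indices(self) -> list[int]:
        removed = set(self.removed_indices)
        return [i for i in range(self.per_sample_mse.size) if i not in removed]


def train_size(n: int, ratio: float) -> int:
    """Number of training samples: round(ratio*n), ties rounded half-up."""
    return int(np.floor(ratio * n + 0.5))


def _maxmin_select(D: np.ndarray, n_train: int) -> list[int]:
    """Sequential max-min selection on a precomputed distance matrix.

    Ties broken toward the lowest index: the initial pair is the
    lexicographically smallest (i, j) attaining the maximum distance; each
    subsequent pick is the lowest-index sample attaining the maximum of the
    minimum distance to the already-selected set.
    """
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = flat.max()
    k = int(np.argmax(flat >= best))  # first (lexicographic) maximal pair
    selected = [int(iu[0][k]), int(iu[1][k])]
    remaining = [i for i in range(n) if i not in selected]
    min_d = D[:, selected].min(axis=1)
    while len(selected) < n_train:
        cand = np.array(remaining)
        pick = int(cand[np.argmax(min_d[cand])])  # argmax takes first on ties
        selected.append(pick)
        remaining.remove(pick)
        min_d = np.minimum(min_d, D[:, pick])
    return selected


def kennard_stone_split(X: np.ndarray, train_fraction: float) -> SplitResult:
    """Kennard–Stone split on Euclidean spectral distances."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = train_size(n, train_fraction)
    if n_train < 2:
        raise ValueError(
            f"train_fraction={train_fraction} yields {n_train} training samples (<2)"
        )
    D = cdist(X, X)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite pairwise distances")
    train = _maxmin_select(D, n_train)
    test = [i for i in range(n) if i not in set(train)]
    return SplitResult(train, test, "ks", train_fraction)


def spxy_split(X: np.ndarray, Y: np.ndarray, train_fraction: float) -> SplitResult:
    """SPXY split: Kennard–Stone on d_X/max(d_X) + d_Y/max(d_Y)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = train_size(n, train_fraction)
    if n_train < 2:
        raise ValueError("train_fraction yields fewer than 2 training samples")
    Dx = cdist(X, X)
    Dy = cdist(Y, Y)
    mx, my = Dx.max(), Dy.max()
    if mx == 0 and my == 0:
        raise ValueError("all joint SPXY distances are zero (constant X and Y)")
    D = (Dx / mx if mx > 0 else Dx) + (Dy / my if my > 0 else Dy)
    train = _maxmin_select(D, n_train)
    test = [i for i in range(n) if i not in set(train)]
    return SplitResult(train, test, "spxy", train_fraction)


def random_split(X: np.ndarray, train_fraction: float, seed: int = 0) -> SplitResult:
    """Seeded uniform random split (the train_test_split comparator)."""
    n = np.atleast_2d(np.asarray(X)).shape[0]
    n_train = train_size(n, train_fraction)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(sorted(int(i) for i in perm[:n_train]),
                       sorted(int(i) for i in perm[n_train:]),
                       "random", train_fraction)


def loo_pls_outlier_screen(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 5,
    threshold: float = 30.0,
) -> OutlierReport:
    """Flag samples whose leave-one-out PLS squared error exceeds a cutoff.

    For each sample i a PLS model is fitted on the remaining samples and the
    squared prediction error at i is recorded; samples with error strictly
    above ``threshold`` are removed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n <= n_components + 1:
        raise ValueError(f"need more than {n_components + 1} samples")
    errors = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X[mask], y[mask])
        yhat = float(pls.predict(X[i][None, :]).ravel()[0])
        errors[i] = (y[i] - yhat) ** 2
        mask[i] = True
    removed = [int(i) for i in np.nonzero(errors > threshold)[0]]
    return OutlierReport(per_sample_mse=errors, removed_indices=removed,
                         threshold=threshold)


def truncate_wavelengths(dataset: SpectraSet, n_first: int) -> SpectraSet:
    """Keep only the first ``n_first`` wavelength points (backend-noise cut)."""
    if not 1 <= n_first <= dataset.n_wavelengths:
        raise ValueError(
            f"n_first must be in [1, {dataset.n_wavelengths}], got {n_first}"
        )
    return SpectraSet(
        X=dataset.X[:, :n_first].copy(),
        wavelengths=dataset.wavelengths[:n_first].copy(),
        Y=dataset.Y.copy(),
        target_names=list(dataset.target_names),
        instrument_id=dataset.instrument_id,
    )


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre each row, scale to unit sample SD."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance row(s) {bad.tolist()}: SNV undefined")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on the reference (default: the column-mean
    spectrum); the corrected row is ``(x - intercept) / slope``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float).ravel()
    if ref.std(ddof=1) == 0:
        raise ValueError("reference spectrum has zero variance: MSC undefined")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        slope = float(ref_c @ (row - row.mean())) / denom
        if slope == 0:
            raise ValueError(f"row {i} has zero regression slope: MSC undefined")
        intercept = row.mean() - slope * ref.mean()
        out[i] = (row - intercept) / slope
    return out


def screen_and_split(
    dataset: SpectraSet,
    target: str | int = 0,
    method: str = "ks",
    ratio: float = 0.8,
    screen_threshold: float | None = None,
    screen_components: int = 5,
    seed: int = 0,
) -> tuple[SpectraSet, SplitResult, OutlierReport | None]:
    """Optional outlier screen followed by a train/test split.

    Returns the (possibly reduced) dataset, the split on it, and the outlier
    report (None when screening is disabled).  Screening precedes splitting.
    """
    report = None
    ds = dataset
    if screen_threshold is not None:
        report = loo_pls_outlier_screen(
            ds.X, ds.target(target), n_components=screen_components,
            threshold=screen_threshold,
        )
        ds = ds.subset(report.kept_indices)
    if method == "ks":
        split = kennard_stone_split(ds.X, ratio)
    elif method == "spxy":
        split = spxy_split(ds.X, ds.Y, ratio)
    elif method == "random":
        split = random_split(ds.X, ratio, seed=seed)
    else:
        raise ValueError(f"unknown split method {method!r}")
    return ds, split, report
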