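"""Core exchange container for spectral datasets.

A :class:`SpectraSet` bundles an absorbance matrix, its wavelength grid,
per-sample reference values and an instrument label.  Every stage of the
toolkit (simulation, I/O, preprocessing, modelling, transfer, evaluation)
consumes and produces this one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SpectraSet"]


@dataclass
class SpectraSet:
    """Absorbance spectra with reference values for one instrument.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_wavelengths)
        Absorbance matrix (a.u.).
    wavelengths : ndarray, shape (n_wavelengths,)
        Strictly increasing wavelength grid in nm.
    Y : ndarray, shape (n_samples, n_targets)
        Reference values (component units), one column per target.
    target_names : list of str
        Column labels for ``Y``.
    instrument_id : str
        Label of the instrument that produced ``X``.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    Y: np.ndarray
    target_names: list[str] = field(default_factory=list)
    instrument_id: str = "unknown"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        if not self.target_names:
            self.target_names = [f"target_{j}" for j in range(self.Y.shape[1])]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but the wavelength grid has "
                f"{self.wavelengths.size} points"
            )
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if len(self.target_names) != self.Y.shape[1]:
            raise ValueError("target_names length must match Y columns")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name, arr in (("X", self.X), ("Y", self.Y), ("wavelengths", self.wavelengths)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def target(self, name_or_index: str | int) -> np.ndarray:
        """Return one reference column as a 1-D array."""
        if isinstance(name_or_index, str):
            try:
                idx = self.target_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"unknown target {name_or_index!r}; have {self.target_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.Y[:, idx]

    def subset(self, indices) -> "SpectraSet":
        """Row-subset (copy) keeping grid, target names and instrument id."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            X=self.X[idx].copy(),
            Y=self.Y[idx].copy(),
            wavelengths=self.wavelengths.copy(),
            target_names=list(self.target_names),
        )

    def copy(self) -> "SpectraSet":
        return self.subset(np.arange(self.n_samples))

    def equals(self, other: "SpectraSet", atol: float = 0.0) -> bool:
        """Field-by-field equality (exact by default)."""
        return (
            self.X.shape == other.X.shape
            and np.allclose(self.X, other.X, atol=atol, rtol=0)
            and np.allclose(self.wavelengths, other.wavelengths, atol=atol, rtol=0)
            and self.Y.shape == other.Y.shape
            and np.allclose(self.Y, other.Y, atol=atol, rtol=0)
            and self.target_names == other.target_names
            and self.instrument_id == other.instrument_id
        )
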