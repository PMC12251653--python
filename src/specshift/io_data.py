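"""Reading and writing SpectraSets.

The native on-disk layout is a single comma-separated UTF-8 text file:

* line 1 (header): ``instrument=<id>``, then the wavelength grid in nm, then
  one ``target:<name>`` cell per reference column;
* one line per sample: sample index, absorbance values, reference values.

Floats are written with ``repr`` (shortest round-trip representation), so
write→read is lossless at full double precision.

An optional reader ingests the public eigenvector MATLAB v5 containers (the
"corn" and "IDRC-2002 shootout" benchmark sets) via :func:`scipy.io.loadmat`.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .data import SpectraSet

__all__ = ["write_spectra", "read_spectra", "read_eigenvector_mat", "FormatError"]


class FormatError(ValueError):
    """Raised when an on-disk file does not match the documented layout."""


def write_spectra(dataset: SpectraSet, path: str | os.PathLike) -> Path:
    """Write a SpectraSet to the delimited-text layout. Returns the path."""
    dataset.validate()
    path = Path(path)
    header = (
        [f"instrument={dataset.instrument_id}"]
        + [repr(float(w)) for w in dataset.wavelengths]
        + [f"target:{name}" for name in dataset.target_names]
    )
    lines = [",".join(header)]
    for i in range(dataset.n_samples):
        row = (
            [str(i)]
            + [repr(float(v)) for v in dataset.X[i]]
            + [repr(float(v)) for v in dataset.Y[i]]
        )
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_spectra(path: str | os.PathLike) -> SpectraSet:
    """Read a SpectraSet written by :func:`write_spectra`."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split(",")
    if not header or not header[0].startswith("instrument="):
        raise FormatError(f"{path}: header must start with 'instrument=<id>'")
    instrument_id = header[0].split("=", 1)[1]
    target_names = [c.split(":", 1)[1] for c in header if c.startswith("target:")]
    n_targets = len(target_names)
    wl_cells = header[1 : len(header) - n_targets]
    try:
        wavelengths = np.array([float(c) for c in wl_cells])
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric wavelength in header ({e})") from None
    n_wl = wavelengths.size
    ncols = 1 + n_wl + n_targets
    X = np.empty((len(lines) - 1, n_wl))
    Y = np.empty((len(lines) - 1, n_targets))
    for li, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != ncols:
            raise FormatError(
                f"{path}: line {li} has {len(cells)} fields, expected {ncols}"
            )
        try:
            vals = [float(c) for c in cells[1:]]
        except ValueError:
            bad = next(c for c in cells[1:] if not _is_number(c))
            raise FormatError(f"{path}: line {li}: non-numeric cell {bad!r}") from None
        X[li - 2] = vals[:n_wl]
        Y[li - 2] = vals[n_wl:]
    try:
        return SpectraSet(
            X=X, wavelengths=wavelengths, Y=Y,
            target_names=target_names, instrument_id=instrument_id,
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from None


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


# ----------------------------------------------------------------------
# Optional: public eigenvector benchmark containers (MATLAB v5)
# ----------------------------------------------------------------------

_CORN_SPECTRA = {"m5": "m5spec", "mp5": "mp5spec", "mp6": "mp6spec"}
_CORN_TARGETS = ("propvals", ["moisture", "oil", "protein", "starch"])
_TABLET_PARTS = ("calibrate", "validate", "test")
_TABLET_TARGETS = ["weight", "hardness", "assay"]


def _extract_data(var) -> np.ndarray:
    """Pull the numeric matrix out of a loadmat'ed dataset object/struct."""
    if isinstance(var, np.ndarray) and var.dtype == float:
        return var
    for attr in ("data",):
        if hasattr(var, attr):
            return np.asarray(getattr(var, attr), dtype=float)
        if isinstance(var, np.ndarray) and var.dtype.names and attr in var.dtype.names:
            return np.asarray(var[attr].item(), dtype=float)
    raise FormatError("variable has no 'data' field and is not a numeric matrix")


def read_eigenvector_mat(path: str | os.PathLike, layout: str) -> dict[str, SpectraSet]:
    """Load the public corn or tablet benchmark MAT container.

    ``layout='corn'`` expects variables ``m5spec``/``mp5spec``/``mp6spec``
    (80x700 spectra) and ``propvals`` (80x4 references); ``layout='tablet'``
    expects ``{calibrate,validate,test}_{1,2,Y}`` and concatenates the three
    parts into one 655-sample set per spectrometer.  Returns a mapping from
    instrument id to SpectraSet.
    """
    from scipy.io import loadmat  # soft dependency kept local

    if layout not in ("corn", "tablet"):
        raise ValueError("layout must be 'corn' or 'tablet'")
    try:
        mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except Exception as e:  # scipy raises assorted errors on truncated files
        raise FormatError(f"{path}: not a readable MATLAB v5 file ({e})") from None

    def require(*names):
        missing = [n for n in names if n not in mat]
        if missing:
            raise FormatError(
                f"{path}: missing expected variables {missing}; found "
                f"{[k for k in mat if not k.startswith('__')]}"
            )

    out: dict[str, SpectraSet] = {}
    if layout == "corn":
        require(*_CORN_SPECTRA.values(), _CORN_TARGETS[0])
        Y = _extract_data(mat[_CORN_TARGETS[0]])
        for inst, var in _CORN_SPECTRA.items():
            X = _extract_data(mat[var])
            wl = 1100.0 + 2.0 * np.arange(X.shape[1])
            out[inst] = SpectraSet(X=X, wavelengths=wl, Y=Y,
                                   target_names=_CORN_TARGETS[1], instrument_id=inst)
    else:
        names = [f"{p}_{s}" for p in _TABLET_PARTS for s in ("1", "2", "Y")]
        require(*names)
        for k, inst in (("1", "A1"), ("2", "A2")):
            X = np.vstack([_extract_data(mat[f"{p}_{k}"]) for p in _TABLET_PARTS])
            Y = np.vstack([np.atleast_2d(_extract_data(mat[f"{p}_Y"]))
                           for p in _TABLET_PARTS])
            wl = 600.0 + 2.0 * np.arange(X.shape[1])
            out[inst] = SpectraSet(X=X, wavelengths=wl, Y=Y,
                                   target_names=_TABLET_TARGETS[: Y.shape[1]],
                                   instrument_id=inst)
    return out
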