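"""Synthetic paired-instrument NIR spectra.

The generator follows the standard linear mixture picture of absorbance
spectroscopy (Beer–Lambert): a sample's spectrum is the concentration-weighted
sum of nonnegative component absorptivity profiles, plus a smooth low-order
baseline and white measurement noise.  A *slave* instrument is derived from
the master by a parametric distortion chain — wavelength shift, resolution
broadening, gain/offset, per-sample multiplicative scatter and noise — the
phenomena that make a calibration model built on one spectrometer fail on
another.

Two preset regimes are provided: ``corn-like`` (80 samples, 700 points on a
1100–2498 nm grid, four mixture targets, a strong master→slave distortion)
and ``tablet-like`` (655 samples, 650 points on a 600–1898 nm grid, one
target, a mild distortion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SpectraSet

__all__ = [
    "AbsorptivityMatrix",
    "InstrumentTransform",
    "SimulatedStudy",
    "generate_component_profiles",
    "generate_master_spectra",
    "apply_instrument_transform",
    "simulate_study",
    "PRESETS",
]


@dataclass
class AbsorptivityMatrix:
    """Component-by-wavelength absorptivity profiles (a.u. per unit conc.)."""

    profiles: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        if self.profiles.shape[1] != self.wavelengths.size:
            raise ValueError("profile columns must match wavelength grid length")
        if not np.all(np.isfinite(self.profiles)):
            raise ValueError("profiles contain non-finite values")
        if np.any(self.profiles < 0):
            raise ValueError("absorptivities must be nonnegative")

    @property
    def n_components(self) -> int:
        return self.profiles.shape[0]


@dataclass
class InstrumentTransform:
    """Parametric master→slave spectral distortion.

    Parameters
    ----------
    shift_nm : float
        Wavelength registration offset; the slave reads the sample at
        ``wavelengths + shift_nm``.
    broaden_sigma_nm : float
        Gaussian smoothing width modelling a coarser optical resolution.
    gain, offset : float
        Global multiplicative factor and additive baseline.
    scatter_sd : float
        Spread of the per-sample multiplicative scatter factor
        ``1 + Normal(0, scatter_sd)``.
    noise_sd : float
        Additive white-noise level (a.u.).
    seed : int
        Seed for the stochastic terms (scatter and noise).
    """

    shift_nm: float = 0.0
    broaden_sigma_nm: float = 0.0
    gain: float = 1.0
    offset: float = 0.0
    scatter_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.broaden_sigma_nm < 0:
            raise ValueError("broaden_sigma_nm must be >= 0")
        if self.scatter_sd < 0 or self.noise_sd < 0:
            raise ValueError("scatter_sd and noise_sd must be >= 0")
        if self.gain == 0:
            raise ValueError("gain must be nonzero")

    def to_dict(self) -> dict:
        return {
            "shift_nm": self.shift_nm,
            "broaden_sigma_nm": self.broaden_sigma_nm,
            "gain": self.gain,
            "offset": self.offset,
            "scatter_sd": self.scatter_sd,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def generate_component_profiles(
    n_components: int,
    wavelengths: np.ndarray,
    peaks_per_component: int = 4,
    peak_width_range: tuple[float, float] = (15.0, 80.0),
    seed: int = 0,
) -> AbsorptivityMatrix:
    """Draw random sum-of-Gaussians absorptivity profiles.

    Each component profile is a sum of ``peaks_per_component`` Gaussian bumps
    with centres uniform on the grid, widths uniform in ``peak_width_range``
    (nm) and unit-order amplitudes; profiles are nonnegative by construction.
    """
    wavelengths = np.asarray(wavelengths, dtype=float).ravel()
    if wavelengths.size < 8:
        raise ValueError("wavelength grid must have at least 8 points")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    lo, hi = peak_width_range
    if lo <= 0 or hi <= 0:
        raise ValueError("peak widths must be positive")
    rng = np.random.default_rng(seed)
    profiles = np.zeros((n_components, wavelengths.size))
    for c in range(n_components):
        centers = rng.uniform(wavelengths[0], wavelengths[-1], peaks_per_component)
        widths = rng.uniform(lo, hi, peaks_per_component)
        amps = rng.uniform(0.3, 1.0, peaks_per_component)
        for mu, sig, a in zip(centers, widths, amps):
            profiles[c] += a * np.exp(-0.5 * ((wavelengths - mu) / sig) ** 2)
    return AbsorptivityMatrix(profiles=profiles, wavelengths=wavelengths)


def generate_master_spectra(
    profiles: AbsorptivityMatrix,
    n_samples: int,
    conc_ranges: list[tuple[float, float]],
    baseline_amp: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_names: list[str] | None = None,
    instrument_id: str = "master",
) -> SpectraSet:
    """Mix component profiles into master-instrument spectra.

    ``X = C @ profiles + baseline + noise`` with concentration rows ``C``
    drawn uniformly from ``conc_ranges`` and ``Y = C``.  The baseline is a
    random quadratic of amplitude ``baseline_amp`` per sample.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(conc_ranges) != profiles.n_components:
        raise ValueError(
            f"need {profiles.n_components} concentration ranges, got {len(conc_ranges)}"
        )
    rng = np.random.default_rng(seed)
    lo = np.array([r[0] for r in conc_ranges], dtype=float)
    hi = np.array([r[1] for r in conc_ranges], dtype=float)
    C = lo + (hi - lo) * rng.random((n_samples, profiles.n_components))
    X = C @ profiles.profiles
    if baseline_amp > 0:
        # smooth per-sample quadratic drift on a [-1, 1] coordinate
        t = np.linspace(-1.0, 1.0, profiles.wavelengths.size)
        coef = rng.uniform(-1.0, 1.0, (n_samples, 3)) * baseline_amp
        X = X + coef[:, [0]] + coef[:, [1]] * t + coef[:, [2]] * t**2
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)
    return SpectraSet(
        X=X,
        wavelengths=profiles.wavelengths,
        Y=C,
        target_names=target_names or [f"component_{j}" for j in range(C.shape[1])],
        instrument_id=instrument_id,
    )


def _gaussian_kernel(sigma_pts: float) -> np.ndarray:
    # truncated at +/- 4 sigma, renormalised to sum 1 (mass conservation)
    half = max(1, int(np.ceil(4.0 * sigma_pts)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_pts) ** 2)
    return k / k.sum()


def apply_instrument_transform(master: SpectraSet, t: InstrumentTransform) -> SpectraSet:
    """Derive a slave-instrument SpectraSet from a master one.

    Per sample: resample at ``wavelengths + shift_nm`` (linear interpolation,
    edge values held), Gaussian-broaden by ``broaden_sigma_nm``, scale by
    ``gain * (1 + scatter_i)``, add ``offset`` and white noise.  Reference
    values are copied unchanged — the sample itself does not change, only the
    instrument reading it.
    """
    wl = master.wavelengths
    span = wl[-1] - wl[0]
    if abs(t.shift_nm) >= span:
        raise ValueError(f"shift_nm={t.shift_nm} exceeds the grid span {span}")
    rng = np.random.default_rng(t.seed)
    X = master.X
    if t.shift_nm != 0.0:
        shifted = np.empty_like(X)
        query = wl + t.shift_nm
        for i in range(X.shape[0]):
            shifted[i] = np.interp(query, wl, X[i])
        X = shifted
    if t.broaden_sigma_nm > 0:
        step = np.diff(wl).mean()
        kernel = _gaussian_kernel(t.broaden_sigma_nm / step)
        pad = kernel.size // 2
        Xp = np.pad(X, ((0, 0), (pad, pad)), mode="edge")
        X = np.array([np.convolve(row, kernel, mode="valid") for row in Xp])
    scatter = rng.normal(0.0, t.scatter_sd, X.shape[0]) if t.scatter_sd > 0 else np.zeros(X.shape[0])
    X = X * (t.gain * (1.0 + scatter))[:, None] + t.offset
    if t.noise_sd > 0:
        X = X + rng.normal(0.0, t.noise_sd, X.shape)
    return SpectraSet(
        X=X,
        wavelengths=wl.copy(),
        Y=master.Y.copy(),
        target_names=list(master.target_names),
        instrument_id=f"{master.instrument_id}->slave",
    )


# ----------------------------------------------------------------------
# Preset study regimes
# ----------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """A master instrument plus one or more distorted slave instruments."""

    master: SpectraSet
    slaves: dict[str, SpectraSet]
    transforms: dict[str, InstrumentTransform]
    profiles: AbsorptivityMatrix = field(repr=False, default=None)


# Mass-fraction concentration ranges typical of ground corn constituents
# (moisture/oil/protein/starch) and of a single-API tablet blend.
_CORN_RANGES = [(0.094, 0.110), (0.031, 0.039), (0.077, 0.098), (0.62, 0.66)]
_CORN_NAMES = ["moisture", "oil", "protein", "starch"]
_TABLET_RANGES = [(0.15, 0.25), (0.40, 0.55), (0.25, 0.40)]
_TABLET_NAMES = ["assay"]

PRESETS = {
    "corn-like": {
        "n_samples": 80,
        "wavelengths": (1100.0, 2.0, 700),
        "n_components": 4,
        "conc_ranges": _CORN_RANGES,
        "target_names": _CORN_NAMES,
        "baseline_amp": 0.005,
        "noise_sd": 0.0005,
        # strong distortion: several times the informative inter-sample
        # signal (~0.007 a.u.), so the master model fails on the slave
        # before transfer while head-retraining can still recover
        "transforms": {
            "slave1": dict(shift_nm=2.0, broaden_sigma_nm=4.0, gain=1.05,
                           offset=0.02, scatter_sd=0.01, noise_sd=0.001),
            "slave2": dict(shift_nm=-2.0, broaden_sigma_nm=5.0, gain=0.95,
                           offset=-0.02, scatter_sd=0.015, noise_sd=0.001),
        },
    },
    "tablet-like": {
        "n_samples": 655,
        "wavelengths": (600.0, 2.0, 650),
        "n_components": 3,
        "conc_ranges": _TABLET_RANGES,
        "target_names": _TABLET_NAMES,
        "baseline_amp": 0.02,
        "noise_sd": 0.001,
        # mild distortion: the two tablet spectrometers read very similarly
        "transforms": {
            "slave1": dict(shift_nm=0.5, broaden_sigma_nm=1.0, gain=1.02,
                           offset=0.01, scatter_sd=0.005, noise_sd=0.001),
        },
    },
}


def simulate_study(preset: str = "corn-like", seed: int = 0) -> SimulatedStudy:
    """Generate a full master-plus-slaves study under a named preset.

    The same physical samples are "measured" on every instrument: slaves are
    distortions of the master spectra and share its reference values.  For the
    tablet-like preset only the first mixture component is reported as the
    target (single-constituent assay); the corn-like preset reports all four.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    start, step, count = p["wavelengths"]
    wl = start + step * np.arange(count)
    profiles = generate_component_profiles(
        p["n_components"], wl, peaks_per_component=4, seed=seed
    )
    master = generate_master_spectra(
        profiles,
        p["n_samples"],
        p["conc_ranges"],
        baseline_amp=p["baseline_amp"],
        noise_sd=p["noise_sd"],
        seed=seed + 1,
        target_names=[f"component_{j}" for j in range(p["n_components"])],
        instrument_id="master",
    )
    # report only the named targets (tablet-like: a single assay column)
    keep = list(range(len(p["target_names"])))
    master = SpectraSet(
        X=master.X,
        wavelengths=master.wavelengths,
        Y=master.Y[:, keep],
        target_names=p["target_names"],
        instrument_id="master",
    )
    slaves: dict[str, SpectraSet] = {}
    transforms: dict[str, InstrumentTransform] = {}
    for k, (name, tp) in enumerate(p["transforms"].items()):
        t = InstrumentTransform(seed=seed + 100 + k, **tp)
        s = apply_instrument_transform(master, t)
        s.instrument_id = name
        slaves[name] = s
        transforms[name] = t
    return SimulatedStudy(master=master, slaves=slaves, transforms=transforms,
                          profiles=profiles)
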