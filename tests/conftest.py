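import numpy as np
import pytest

from specshift.data import SpectraSet
from specshift.synth import (
    InstrumentTransform,
    generate_component_profiles,
    generate_master_spectra,
)


@pytest.fixture(scope="session")
def wavelengths():
    """A 120-point uniform 2 nm grid (small stand-in for a full NIR grid)."""
    return 1100.0 + 2.0 * np.arange(120)


@pytest.fixture(scope="session")
def profiles(wavelengths):
    return generate_component_profiles(3, wavelengths, peaks_per_component=3, seed=7)


@pytest.fixture()
def master_set(profiles):
    """A small noiseless master dataset with 3 mixture components."""
    return generate_master_spectra(
        profiles,
        n_samples=24,
        conc_ranges=[(0.1, 0.3), (0.2, 0.6), (0.5, 1.0)],
        baseline_amp=0.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture()
def identity_transform():
    return InstrumentTransform()


@pytest.fixture()
def tiny_set():
    """Four samples, eight wavelengths; handy for exact I/O checks."""
    rng = np.random.default_rng(3)
    return SpectraSet(
        X=rng.random((4, 8)),
        wavelengths=np.linspace(900.0, 914.0, 8),
        Y=rng.random((4, 2)),
        target_names=["a", "b"],
        instrument_id="toy",
    )
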