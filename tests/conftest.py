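import numpy as np
import pytest

from sersml import (
    BandSpec,
    SpectrumSet,
    SyntheticClassProfile,
    preset_profiles,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def axis():
    """A short wavenumber axis for cheap tests."""
    return np.arange(400.0, 1800.0, 2.0)


@pytest.fixture(scope="session")
def quiet_profile():
    """Single-band, noise-free profile for exact-value checks."""
    return SyntheticClassProfile(
        name="quiet",
        bands=[BandSpec(center=1349.0, amplitude_mean=100.0, fwhm=10.0)],
    )


@pytest.fixture(scope="session")
def two_class_set():
    """Small two-class synthetic set on the default axis (30 spectra)."""
    return simulate_dataset(
        preset_profiles(["a549-like", "beas2b-like"]), n_per_class=15, seed=11
    )


@pytest.fixture()
def random_set(axis):
    rng = np.random.default_rng(5)
    n = 6
    return SpectrumSet(
        axis,
        rng.normal(50.0, 5.0, (n, axis.size)),
        np.array(["A549", "BEAS-2B"] * 3, dtype=object),
        np.array([f"s{i}" for i in range(n)], dtype=object),
    )
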