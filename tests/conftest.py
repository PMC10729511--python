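import numpy as np
import pytest

from ramanpat import SpectraSet, Spectrum, generate_run


@pytest.fixture
def rng():
    return np.random.default_rng(20231218)


@pytest.fixture
def small_set(rng):
    """12 random spectra on a 120-channel descending axis."""
    w = np.linspace(1800, 600, 120)
    y = rng.normal(1.0, 0.2, size=(12, 120)) + np.abs(rng.normal(size=(12, 1)))
    t = np.arange(12) / 3.0
    return SpectraSet(w, y, t)


@pytest.fixture
def random_spectrum(rng):
    w = np.linspace(3000, 600, 200)
    return Spectrum(w, rng.normal(2.0, 0.5, size=200))


@pytest.fixture(scope="session")
def default_run():
    """The seeded default synthetic glucose fermentation (expensive; shared)."""
    return generate_run("rhodotorula_glucose", seed=1, replicate="control")
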