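import numpy as np
import pytest

from otnmr import ComponentLibrary, Spectrum


def _random_spectrum(rng, n_max=10, lo=0.0, hi=10.0):
    n = int(rng.integers(2, n_max + 1))
    xs = np.sort(rng.uniform(lo, hi, n))
    # re-draw until strictly distinct (uniform draws collide with prob ~0)
    ws = rng.uniform(0.05, 1.0, n)
    ws /= ws.sum()
    return Spectrum(xs, ws, normalized=True)


@pytest.fixture
def random_spectrum():
    """Factory: seeded random normalized spectra with small support."""
    return _random_spectrum


@pytest.fixture
def random_instance():
    """Factory: seeded random (mixture, library) deconvolution instances."""

    def make(rng, k_max=3, n_max=8, lo=0.0, hi=10.0):
        k = int(rng.integers(1, k_max + 1))
        comps = tuple(
            _random_spectrum(rng, n_max=n_max, lo=lo, hi=hi).with_label(f"c{i}")
            for i in range(k)
        )
        library = ComponentLibrary(comps)
        mixture = _random_spectrum(rng, n_max=n_max, lo=lo, hi=hi)
        return mixture, library

    return make


@pytest.fixture
def delta():
    """A unit point mass at a given ppm position."""

    def make(x):
        return Spectrum([x], [1.0], normalized=True)

    return make
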