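import numpy as np
import pytest

from optibiopsy import synthetic
from optibiopsy.spectra_io import AF, DRS, Spectrum


@pytest.fixture()
def drs_spectrum():
    wl = np.arange(500.0, 1121.0)
    return Spectrum(wl, 1.0 + 0.001 * (wl - 500.0), DRS, "reflectance")


@pytest.fixture(scope="session")
def small_config():
    """A small but complete synthetic study: both classes, deterministic."""
    return synthetic.GeneratorConfig(n_healthy=6, n_tumor=7, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """A generated on-disk dataset shared across I/O-level tests."""
    root = tmp_path_factory.mktemp("dataset")
    manifest = synthetic.generate_dataset(small_config, root / "sim")
    return manifest, root / "sim"


def random_spectrum(rng, modality=DRS, n_min=2, n_max=60):
    """A random valid spectrum: sorted distinct wavelengths, finite values."""
    n = int(rng.integers(n_min, n_max + 1))
    wl = np.sort(rng.uniform(300.0, 1200.0, size=n))
    while np.any(np.diff(wl) == 0):  # pragma: no cover - vanishing probability
        wl = np.sort(rng.uniform(300.0, 1200.0, size=n))
    values = rng.normal(0.0, 100.0, size=n)
    excitation = 415.0 if modality == AF else None
    return Spectrum(wl, values, modality, "raw", excitation)
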