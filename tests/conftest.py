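import numpy as np
import pytest

from spectrofibro.io import SpectralImage, WavenumberAxis
from spectrofibro.synth import (PhantomConfig, default_endmembers,
                                make_phantom, synth_spectrum)


@pytest.fixture(scope="session")
def axis_fingerprint() -> WavenumberAxis:
    """900-1800 cm^-1 at 2 cm^-1 spacing (whole-sample analysis grid)."""
    return WavenumberAxis(np.arange(900.0, 1801.0, 2.0))


@pytest.fixture(scope="session")
def endmembers():
    return default_endmembers()


@pytest.fixture(scope="session")
def endmember_spectra(endmembers, axis_fingerprint):
    return {name: synth_spectrum(em, axis_fingerprint)
            for name, em in endmembers.items()}


@pytest.fixture(scope="session")
def phantom30():
    """One 64x64 phantom at 30% fibrosis with all paired artifacts."""
    config = PhantomConfig(fibrosis_percent=30.0, seed=7)
    truth, cube, paraffin, trichrome = make_phantom(config)
    return config, truth, cube, paraffin, trichrome


def small_image(spectra: np.ndarray, axis: WavenumberAxis,
                shape=None) -> SpectralImage:
    """Wrap an (N, B) spectra matrix as an Nx1 spectral image."""
    n = spectra.shape[0]
    if shape is None:
        shape = (n, 1)
    return SpectralImage(spectra.reshape(shape[0], shape[1], -1), axis)
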