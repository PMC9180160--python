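import numpy as np
import pytest

from nirclass import Mode, SpectraSet, Spectrum
from nirclass.synth import SynthConfig, generate_tea_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid():
    """Short descending wavenumber grid."""
    return np.linspace(10_000.0, 4_000.0, 60)


@pytest.fixture
def absorbance_set(grid, rng):
    """Small unlabeled absorbance set on the short grid."""
    values = 0.5 + 0.2 * rng.random((5, grid.size))
    return SpectraSet(wavenumbers=grid, values=values, mode=Mode.ABSORBANCE)


@pytest.fixture
def small_tea_set():
    """Reduced synthetic tea panel: 6 classes x 6 samples, 200 points."""
    cfg = SynthConfig(samples_per_class=6, n_points=200, seed=7)
    return generate_tea_spectra(cfg)


def make_spectrum(grid, values, mode=Mode.ABSORBANCE, **kw):
    return Spectrum(wavenumbers=grid, values=values, mode=mode, **kw)
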