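import numpy as np
import pytest

from nirspeclib import GeneratorSpec, Spectrum, generate_library
from nirspeclib.spectra import CANONICAL_GRID

BALANCED_150 = {
    "tablet": 30,
    "dispersible_tablet": 30,
    "chewable_tablet": 30,
    "granule": 30,
    "oral_suspension": 30,
}


def make_spectrum(values, grid=None, **meta) -> Spectrum:
    """Small helper: spectrum from a value array on a uniform grid."""
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = 4000.0 + 4.0 * np.arange(values.size)
    return Spectrum(wavenumbers=np.asarray(grid, dtype=float), absorbance=values, **meta)


@pytest.fixture(scope="session")
def small_library():
    """A 60-entry indexed synthetic library (12 per form), session-cached."""
    counts = {f: 12 for f in BALANCED_150}
    return generate_library(GeneratorSpec(n_per_form=counts, seed=0))


@pytest.fixture(scope="session")
def library150():
    """The 150-entry balanced library used by the pipeline-level tests."""
    return generate_library(GeneratorSpec(n_per_form=BALANCED_150, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def canonical_grid():
    return CANONICAL_GRID
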