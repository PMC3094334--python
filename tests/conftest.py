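import numpy as np
import pytest

from woodspec import SimConfig, simulate_dataset
from woodspec.spectra_io import SpectraSet, Spectrum


@pytest.fixture(scope="session")
def small_dataset():
    """20 simulated samples with both reference tables (seed fixed)."""
    return simulate_dataset(SimConfig(n_samples=20, seed=7))


@pytest.fixture()
def toy_spectrum():
    wn = np.arange(2000.0, 700.0 - 1, -4.0)
    ab = 0.5 + 0.3 * np.exp(-0.5 * ((wn - 1500.0) / 30.0) ** 2)
    return Spectrum(wn, ab, "toy")


def make_set(matrix, grid, ids=None):
    ids = ids or [f"s{i}" for i in range(matrix.shape[0])]
    return SpectraSet.from_matrix(np.asarray(grid, float), np.asarray(matrix, float), ids)
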