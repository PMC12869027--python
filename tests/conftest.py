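import numpy as np
import pytest

from patquant import (PHANTOM_GRID, Spectrum, WavelengthGrid,
                      load_default_table)


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def phantom_grid():
    return PHANTOM_GRID


@pytest.fixture(scope="session")
def clinical_grid():
    return WavelengthGrid(np.array([750.0, 780.0, 800.0, 830.0]))


def make_synthetic_eigenspectra(grid, slopes=(-0.0015, 0.0005, -0.0005)):
    """Small constructed eigenspectra set: smooth exponential-tilt members
    normalized at 800 nm (synthetic stand-ins for simulated fluence spectra)."""
    from patquant import EigenspectraSet
    members = []
    for s in slopes:
        amp = np.exp(s * (grid.values - 800.0))
        members.append(Spectrum(grid, amp / amp[grid.index_of(800.0)]))
    ave = np.mean([m.amplitudes for m in members], axis=0)
    ave = ave / ave[grid.index_of(800.0)]
    return EigenspectraSet(members, Spectrum(grid, ave), 800.0,
                           provenance="synthetic exponential tilts")


@pytest.fixture
def synthetic_eig(phantom_grid):
    return make_synthetic_eigenspectra(phantom_grid)
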