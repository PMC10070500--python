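import numpy as np
import pytest

from ramanstains.spectra import AxisSpec, Spectrum
from ramanstains.synthdata import make_disjoint_substrate, make_reference


@pytest.fixture(scope="session")
def axis():
    return AxisSpec()


@pytest.fixture(scope="session")
def grid(axis):
    return axis.grid()


@pytest.fixture(scope="session")
def blood():
    return make_reference("blood")


@pytest.fixture(scope="session")
def denim():
    return make_reference("denim")


@pytest.fixture(scope="session")
def disjoint_substrate():
    """Substrate whose bands avoid every blood band (absence-test control)."""
    return make_disjoint_substrate()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_spectrum(values, start=400.0, step=1.0, label=""):
    """Short hand-constructed spectra for oracle examples (any length)."""
    values = np.asarray(values, dtype=float)
    ax = start + step * np.arange(values.size)
    if values.size >= 8:
        return Spectrum(ax, values, label)
    return Spectrum._unchecked(ax, values, label)
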