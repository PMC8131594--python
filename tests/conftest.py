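import numpy as np
import pytest

from derheo.io import FrequencySweep
from derheo.pipeline import band_grid, default_cantilever, default_cell


@pytest.fixture(scope="session")
def f_grid():
    """The standard measurement grid, 1-38 kHz at 200 Hz."""
    return band_grid()


@pytest.fixture
def cell():
    return default_cell()


@pytest.fixture
def cantilever():
    return default_cantilever()


@pytest.fixture
def make_sweep():
    def _make(frequencies, amplitudes, phases, label="MM", **kw):
        return FrequencySweep(np.asarray(frequencies, float),
                              np.asarray(amplitudes, float),
                              np.asarray(phases, float), label, **kw)
    return _make
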