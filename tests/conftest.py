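import numpy as np
import pytest

from ftircell import (WavenumberGrid, build_band_library,
                      generate_calibration_set)


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid.default()


@pytest.fixture(scope="session")
def library():
    return build_band_library()


@pytest.fixture(scope="session")
def calibration(grid, library):
    """Default 30-spectrum calibration campaign, fixed seed."""
    return generate_calibration_set(library=library, grid=grid, rng=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
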