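import numpy as np
import pytest

from ttmorph.simulate import SimTruth, generate_cell


@pytest.fixture(scope="session")
def default_cell():
    """One synthetic cell at the default study conditions."""
    return generate_cell(SimTruth(seed=11))


@pytest.fixture(scope="session")
def clean_cell():
    """A near-noiseless synthetic cell (high photon count, no read noise)."""
    return generate_cell(SimTruth(seed=11, photon_scale=1e5, read_noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
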