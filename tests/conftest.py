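import numpy as np
import pytest

import colribbon as cb


@pytest.fixture
def small_rod():
    """10-bead default-motif rod (one full charge-motif repeat)."""
    return cb.collagen_mimetic_rod(n_beads=10)


@pytest.fixture
def model_params():
    return cb.ModelParams(es=cb.default_electrostatics(),
                          lj=cb.default_lj(),
                          surf=cb.default_surface())


@pytest.fixture
def rng():
    return np.random.default_rng(20240703)
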