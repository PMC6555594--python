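import numpy as np
import pytest

from smcortex import synthetic as syn


@pytest.fixture
def wt_populations():
    """Two-population mixture mirroring the wild-type generator truth."""
    return [
        syn.KineticPopulation("fast", k_off=1.0 / 1.1, diffusion_coeff=0.31, fraction=0.76),
        syn.KineticPopulation("slow", k_off=1.0 / 3.1, diffusion_coeff=0.01, fraction=0.24),
    ]


@pytest.fixture
def continuous_scheme():
    """Continuous 20 ms imaging with bleaching."""
    return syn.ImagingScheme(tau_int=0.02, delay=0.0, k_bleach=3.0)


@pytest.fixture
def geometry():
    return syn.CellGeometryModel(length=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
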