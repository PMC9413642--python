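import numpy as np
import pytest

from tissueoptics.diffusion_fem import build_mesh
from tissueoptics.synthetic_data import PRESET_TABLE, make_preset


@pytest.fixture(scope="session")
def all_presets():
    """All 12 tissue/wavelength presets."""
    return [make_preset(t, w) for (t, w) in sorted(PRESET_TABLE)]


@pytest.fixture(scope="session")
def brain_532():
    return make_preset("brain", 532)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Coarse FEM mesh shared by inversion tests."""
    return build_mesh(0.05)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220818)
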