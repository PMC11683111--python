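import numpy as np
import pytest

import eamap


@pytest.fixture(scope="session")
def disc_mesh():
    """Medium-resolution disc: radius 40 mm, ~2 mm edges."""
    return eamap.make_mesh("disc", 2.0, 40.0)


@pytest.fixture(scope="session")
def coarse_disc():
    """Small cheap disc for plumbing tests."""
    return eamap.make_mesh("disc", 4.0, 20.0)


@pytest.fixture(scope="session")
def planar_truth(disc_mesh):
    return eamap.simulate_activation(disc_mesh, "planar", 0.7, direction=(1, 0, 0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
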