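import numpy as np
import pytest

import thzpol as tp


@pytest.fixture(scope="session")
def geometry():
    return tp.IncidenceGeometry(theta_deg=30.0, n_incident=1.0)


@pytest.fixture(scope="session")
def block_optics():
    return tp.default_optics_map("block")


@pytest.fixture(scope="session")
def demo_labels():
    return tp.make_label_map(tp.demo_block_phantom(16, 16))


@pytest.fixture(scope="session")
def clean_grid41():
    """Noise-free, leak-free acquisition on the 41-bin frequency grid."""
    return tp.AcquisitionConfig.grid_41(noise_sigma=0.0, epsilon_leakage=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_block_cube(demo_labels, block_optics, geometry, clean_grid41):
    return tp.simulate_scan(demo_labels, block_optics, geometry, clean_grid41,
                            medium="block")


@pytest.fixture(scope="session")
def random_scattering_matrices():
    rng = np.random.default_rng(1234)
    return rng.normal(size=(2000, 2, 2)) + 1j * rng.normal(size=(2000, 2, 2))
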