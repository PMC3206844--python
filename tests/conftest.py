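import numpy as np
import pytest

import saxskit as sk


@pytest.fixture(scope="session")
def q_grid():
    return sk.default_q_grid()


@pytest.fixture(scope="session")
def small_sphere():
    """300-bead sphere of radius 15 A, shared across read-only tests."""
    return sk.make_bead_sphere(15.0, 300, seed=7)


@pytest.fixture(scope="session")
def two_component_assembly():
    """Small two-lobe assembly for geometry and refinement tests."""
    return sk.make_two_lobe_dimer(lobe_radius=8.0, separation=20.0,
                                  n_beads_per_lobe=60, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
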