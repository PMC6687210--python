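import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_element_model():
    """FemModel over the two-unit-cube fixture (FD consistency checks)."""
    from shellgrow.engine import grid_from_strip_mesh
    from shellgrow.fixtures import make_two_element_mesh
    from shellgrow.mechanics import FemModel

    mesh = make_two_element_mesh()
    grid = grid_from_strip_mesh(mesh)
    return mesh, grid, FemModel(grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
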