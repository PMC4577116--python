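import numpy as np
import pytest

import pcmech as pm
from pcmech.materials import MaterialParams


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def small_rve():
    """A small unit-cube RVE network with face cross-links (~60 fibers)."""
    return pm.generate_rve_network((40, 80), np.eye(3), seed=42)


@pytest.fixture(scope="session")
def tiny_isolated_mesh():
    return pm.mesh_half_ellipsoid(pm.CorpuscleGeometry(), resolution=2)


def two_node_network(p0, p1, rest_length, boundary=(True, True)):
    """Single-fiber network helper for closed-form stress checks."""
    return pm.FiberNetwork(
        node_coords=np.array([p0, p1], dtype=float),
        fibers=np.array([[0, 1]], dtype=np.int32),
        rest_lengths=np.array([float(rest_length)]),
        boundary_mask=np.array(boundary, dtype=bool),
    )
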