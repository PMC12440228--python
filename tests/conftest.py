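import numpy as np
import pytest

from tonguefem import (Mesh, PhantomSpec, generate_tongue_phantom,
                       promote_tet4)


@pytest.fixture(scope="session")
def default_phantom():
    """The default tongue phantom (~3000 TET10 nodes)."""
    return generate_tongue_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    """A coarse phantom for solver tests (fast)."""
    return generate_tongue_phantom(PhantomSpec(resolution=12.0))


@pytest.fixture(scope="session")
def half_phantom():
    """Symmetric half phantom with the mid-sagittal node set."""
    return generate_tongue_phantom(PhantomSpec(symmetric_half=True))


@pytest.fixture()
def single_tet():
    """One TET10 element spanning a 10 mm right tetrahedron."""
    nodes = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                      [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]])
    coords, conn = promote_tet4(nodes, np.array([[0, 1, 2, 3]]))
    return Mesh(coords, conn)


@pytest.fixture()
def two_tet_bar():
    """Two TET10 elements forming a small bar-like patch."""
    nodes = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0],
                      [0.0, 0.0, 10.0], [10.0, 10.0, 10.0]])
    coords, conn = promote_tet4(
        nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
    return Mesh(coords, conn)
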