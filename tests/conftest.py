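import numpy as np
import pytest

from osteoadapt import LoadCase, RemodelParams, build_grid, builtin_laws
from osteoadapt.mesh import GridMesh


@pytest.fixture(scope="session")
def laws():
    return builtin_laws()


@pytest.fixture(scope="session")
def mesh4():
    """4^3-element cube, full 5 mm domain (fast FE tests)."""
    return build_grid(5.0, 1.25)


@pytest.fixture(scope="session")
def mesh5():
    """5^3-element cube, full 5 mm domain (kernel/trajectory tests)."""
    return build_grid(5.0, 1.0)


@pytest.fixture
def single_element_mesh():
    return build_grid(1.0, 1.0)


def make_line_mesh(n_elements: int, h: float = 1.0) -> GridMesh:
    """Hand-built 1D row of cubic elements (only centroids matter for
    kernel/neighbor tests; connectivity is a minimal valid brick row)."""
    m = n_elements + 1
    nodes = []
    for iz in range(2):
        for iy in range(2):
            for ix in range(m):
                nodes.append((ix * h, iy * h, iz * h))
    nodes = np.array(nodes, dtype=float)

    def nid(ix, iy, iz):
        return ix + m * iy + 2 * m * iz

    conn = np.array(
        [
            [
                nid(e, 0, 0),
                nid(e + 1, 0, 0),
                nid(e + 1, 1, 0),
                nid(e, 1, 0),
                nid(e, 0, 1),
                nid(e + 1, 0, 1),
                nid(e + 1, 1, 1),
                nid(e, 1, 1),
            ]
            for e in range(n_elements)
        ],
        dtype=np.int64,
    )
    centroids = nodes[conn].mean(axis=1)
    top = np.flatnonzero(np.abs(nodes[:, 1] - h) < 1e-12)
    bottom = np.flatnonzero(np.abs(nodes[:, 1]) < 1e-12)
    return GridMesh(
        node_coordinates=nodes,
        element_connectivity=conn,
        element_edge_mm=h,
        n_elements_per_axis=n_elements,
        element_centroids=centroids,
        node_sets={"TOP_FACE": top, "BOTTOM_FACE": bottom},
    )


@pytest.fixture
def baseline_params():
    return RemodelParams()


@pytest.fixture
def graded_load():
    return LoadCase(p_max=10.0, profile="graded")


@pytest.fixture
def uniform_load():
    return LoadCase(p_max=10.0, profile="uniform")
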