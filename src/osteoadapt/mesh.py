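"""Structured voxel hexahedral mesh of the cube domain.

Conventions (fixed, so that runs are bit-reproducible):

* Origin at a cube corner.  ``x`` in [0, L] is the load-gradient axis
  (surface pressure is maximal at x = 0), ``y`` in [0, L] is the vertical
  loading axis, ``z`` in [0, L] is the uniform axis.
* Node numbering is lexicographic with x fastest, then y, then z:
  ``node_id = ix + (n+1)*iy + (n+1)^2*iz``.
* Element numbering likewise: ``elem_id = ex + n*ey + n^2*ez``.
* Local node ordering of each 8-node brick follows the VTK hexahedron
  convention: the quad at the lower-z face counter-clockwise (viewed from
  +z), then the corresponding quad at the upper-z face::

      0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0)
      4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1)

  (offsets in element-grid steps).  This ordering has a positive, constant
  Jacobian for axis-aligned cubes and is shared by the stiffness code and
  the VTK export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["GridMesh", "build_grid", "neighbor_pairs", "mirror_map_z"]

#: local corner offsets (element-grid steps) in the documented ordering
_LOCAL_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class GridMesh:
    """Structured voxel mesh of an axis-aligned cube.

    Attributes
    ----------
    node_coordinates : (n_nodes, 3) float array, mm
    element_connectivity : (n_elements, 8) int array
        Node indices per element in the documented local ordering.
    element_edge_mm : float
        Edge length h of every (cubic) element.
    n_elements_per_axis : int
        Number of elements n along each axis; the mesh has n^3 elements
        and (n+1)^3 nodes.
    element_centroids : (n_elements, 3) float array, mm
    node_sets : dict
        Named node index sets; always contains ``TOP_FACE`` (y = L) and
        ``BOTTOM_FACE`` (y = 0).
    """

    node_coordinates: np.ndarray
    element_connectivity: np.ndarray
    element_edge_mm: float
    n_elements_per_axis: int
    element_centroids: np.ndarray
    node_sets: dict = field(default_factory=dict)

    @property
    def cube_edge_mm(self) -> float:
        return self.element_edge_mm * self.n_elements_per_axis

    @property
    def n_nodes(self) -> int:
        return self.node_coordinates.shape[0]

    @property
    def n_elements(self) -> int:
        return self.element_connectivity.shape[0]

    def element_grid_indices(self) -> np.ndarray:
        """(n_elements, 3) integer (ex, ey, ez) per element id."""
        n = self.n_elements_per_axis
        ids = np.arange(self.n_elements)
        ex = ids % n
        ey = (ids // n) % n
        ez = ids // (n * n)
        return np.stack([ex, ey, ez], axis=1)


def build_grid(cube_edge_mm: float, element_edge_mm: float) -> GridMesh:
    """Build the structured voxel mesh of a cube.

    Parameters
    ----------
    cube_edge_mm : float
        Edge length L of the cube domain, mm.
    element_edge_mm : float
        Edge length h of each cubic element, mm.  L/h must be an integer
        (within rounding tolerance).

    Raises
    ------
    ValueError
        If either length is non-positive or L/h is not an integer.
    """
    if cube_edge_mm <= 0 or element_edge_mm <= 0:
        raise ValueError(
            f"cube_edge_mm ({cube_edge_mm}) and element_edge_mm "
            f"({element_edge_mm}) must both be positive"
        )
    ratio = cube_edge_mm / element_edge_mm
    n = int(round(ratio))
    if n < 1 or abs(ratio - n) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"cube edge {cube_edge_mm} mm is not an integer multiple of "
            f"element edge {element_edge_mm} mm (ratio {ratio})"
        )

    h = element_edge_mm
    m = n + 1  # nodes per axis
    # node coordinates, x fastest
    ix, iy, iz = np.meshgrid(np.arange(m), np.arange(m), np.arange(m), indexing="ij")
    order = np.argsort(ix.ravel() + m * iy.ravel() + m * m * iz.ravel(), kind="stable")
    nodes = (
        np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)[order].astype(float) * h
    )

    # element connectivity
    ids = np.arange(n**3)
    ex = ids % n
    ey = (ids // n) % n
    ez = ids // (n * n)
    corner = np.stack([ex, ey, ez], axis=1)  # (ne, 3)
    conn = np.empty((n**3, 8), dtype=np.int64)
    for a, off in enumerate(_LOCAL_OFFSETS):
        g = corner + off
        conn[:, a] = g[:, 0] + m * g[:, 1] + m * m * g[:, 2]

    centroids = nodes[conn].mean(axis=1)

    L = n * h
    ytol = 1e-9 * max(1.0, L)
    node_sets = {
        "TOP_FACE": np.flatnonzero(np.abs(nodes[:, 1] - L) <= ytol),
        "BOTTOM_FACE": np.flatnonzero(np.abs(nodes[:, 1]) <= ytol),
    }
    return GridMesh(
        node_coordinates=nodes,
        element_connectivity=conn,
        element_edge_mm=h,
        n_elements_per_axis=n,
        element_centroids=centroids,
        node_sets=node_sets,
    )


def neighbor_pairs(mesh: GridMesh, radius_mm: float):
    """All ordered centroid pairs (i, j, distance) with distance <= radius.

    Includes self-pairs (i, i, 0.0) and both orderings of each distinct
    pair, so the result is symmetric.  Returns arrays ``(i, j, dist)``.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    tree = cKDTree(mesh.element_centroids)
    pairs = tree.query_pairs(radius_mm, output_type="ndarray")  # i < j
    ne = mesh.n_elements
    i = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(ne)])
    j = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(ne)])
    d = np.linalg.norm(
        mesh.element_centroids[i] - mesh.element_centroids[j], axis=1
    )
    order = np.lexsort((j, i))
    return i[order], j[order], d[order]


def mirror_map_z(mesh: GridMesh) -> np.ndarray:
    """Element index map of the mirror reflection about the mid-z plane.

    ``rho[mirror_map_z(mesh)]`` is the density field reflected through
    z = L/2; the structured mesh is always symmetric about that plane.
    """
    n = mesh.n_elements_per_axis
    g = mesh.element_grid_indices()
    return g[:, 0] + n * g[:, 1] + n * n * (n - 1 - g[:, 2])
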