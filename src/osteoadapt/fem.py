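"""Linear isotropic elasticity on the voxel mesh.

Small-strain, linear elastic, isotropic continuum discretized with
8-node trilinear brick elements (2x2x2 Gauss quadrature for stiffness).
Units are mm-N-MPa throughout; with apparent density in g/cm^3 the
per-element strain energy density (SED) comes out in MPa = J/cm^3, so
the remodeling stimulus SED/rho is in J/g directly.

Boundary conditions of the cube benchmark: a compressive surface
pressure acts in -y on the whole top face, decreasing linearly from
p_max at x = 0 to zero at x = L (optionally uniform); the bottom face is
fixed in the vertical (y) direction.  That alone leaves two lateral
translations and one rotation about y unconstrained, so three auxiliary
point constraints are added: x and z at the bottom corner node (0,0,0)
and z at the bottom corner node (L,0,0).  Homogeneous strain states are
compatible with these pins, so uniform-pressure patch tests are exact.

A solve that fails to factorize, returns non-finite values, or leaves a
relative equilibrium residual above 1e-4 is reported with status
``UNSOLVABLE`` rather than raising: remodeling runs must be able to
record that a density distribution became unsolvable and stop cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import GridMesh

__all__ = [
    "LoadCase",
    "FemSolution",
    "CubeElasticityModel",
    "element_stiffness",
    "consistent_surface_loads",
    "assemble_and_solve",
    "element_sed",
]

#: natural-coordinate signs of the 8 local nodes (matches mesh ordering)
_SIGNS = np.array(
    [
        (-1, -1, -1),
        (1, -1, -1),
        (1, 1, -1),
        (-1, 1, -1),
        (-1, -1, 1),
        (1, -1, 1),
        (1, 1, 1),
        (-1, 1, 1),
    ],
    dtype=float,
)

#: local node indices of the +y (top) element face
_TOP_FACE_LOCAL = np.array([3, 2, 7, 6])

_GAUSS = 1.0 / np.sqrt(3.0)

# relative equilibrium residual above which a solve is declared unsolvable
UNSOLVABLE_RESIDUAL = 1e-4


@dataclass(frozen=True)
class LoadCase:
    """Top-face compressive pressure profile.

    ``profile="graded"`` is the benchmark load p(x) = p_max * (1 - x/L),
    uniform in z; ``profile="uniform"`` applies p_max everywhere (used by
    patch tests and the homeostatic-pressure check).  Pressure acts in -y.
    """

    p_max: float
    profile: str = "graded"

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise ValueError(f"p_max must be >= 0, got {self.p_max}")
        if self.profile not in ("graded", "uniform"):
            raise ValueError(f"unknown load profile {self.profile!r}")

    def pressure(self, x, cube_edge_mm: float):
        """Pressure magnitude (N/mm^2) at coordinate(s) x on the top face."""
        x = np.asarray(x, dtype=float)
        if self.profile == "uniform":
            return np.full_like(x, self.p_max)
        return self.p_max * (1.0 - x / cube_edge_mm)


@dataclass
class FemSolution:
    """Result of one elasticity solve."""

    displacements: np.ndarray  # (n_nodes, 3), mm
    sed: np.ndarray  # (n_elements,), MPa = J/cm^3
    status: str  # "OK" | "UNSOLVABLE"
    residual_norm: float
    message: str = ""


def isotropic_elasticity_matrix(modulus_mpa: float, poisson: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    lam = modulus_mpa * poisson / ((1 + poisson) * (1 - 2 * poisson))
    mu = modulus_mpa / (2 * (1 + poisson))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _shape_gradients(xi: float, eta: float, zeta: float, edge_mm: float) -> np.ndarray:
    """dN_i/dx (3, 8) at a natural-coordinate point, for a cube of edge h."""
    s = _SIGNS
    dn = np.empty((3, 8))
    dn[0] = s[:, 0] * (1 + eta * s[:, 1]) * (1 + zeta * s[:, 2]) / 8.0
    dn[1] = s[:, 1] * (1 + xi * s[:, 0]) * (1 + zeta * s[:, 2]) / 8.0
    dn[2] = s[:, 2] * (1 + xi * s[:, 0]) * (1 + eta * s[:, 1]) / 8.0
    return dn * (2.0 / edge_mm)  # constant Jacobian h/2 per axis


def _strain_displacement(dn_dx: np.ndarray) -> np.ndarray:
    """6x24 B matrix from shape-function gradients (engineering shears)."""
    B = np.zeros((6, 24))
    for i in range(8):
        dx, dy, dz = dn_dx[:, i]
        c = 3 * i
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


@lru_cache(maxsize=8)
def _unit_element_stiffness(edge_mm: float, poisson: float) -> np.ndarray:
    """24x24 brick stiffness for unit Young's modulus (2x2x2 Gauss)."""
    C = isotropic_elasticity_matrix(1.0, poisson)
    detJ = (edge_mm / 2.0) ** 3
    K = np.zeros((24, 24))
    for xi in (-_GAUSS, _GAUSS):
        for eta in (-_GAUSS, _GAUSS):
            for zeta in (-_GAUSS, _GAUSS):
                B = _strain_displacement(_shape_gradients(xi, eta, zeta, edge_mm))
                K += B.T @ C @ B * detJ
    return 0.5 * (K + K.T)


def element_stiffness(edge_mm: float, modulus_mpa: float, poisson: float) -> np.ndarray:
    """24x24 stiffness matrix of one cubic element (N/mm per mm)."""
    if edge_mm <= 0 or modulus_mpa <= 0:
        raise ValueError("edge_mm and modulus_mpa must be positive")
    if not 0 < poisson < 0.5:
        raise ValueError(f"poisson must lie in (0, 0.5), got {poisson}")
    return modulus_mpa * _unit_element_stiffness(float(edge_mm), float(poisson))


def consistent_surface_loads(mesh: GridMesh, load: LoadCase) -> np.ndarray:
    """Consistent nodal force vector (n_nodes*3,) for the top-face pressure.

    The pressure profile is integrated against the bilinear shape
    functions of each top-face facet with 2x2 Gauss quadrature, exact for
    a linear-in-x pressure.  Forces act in -y on TOP_FACE nodes only.
    """
    n = mesh.n_elements_per_axis
    h = mesh.element_edge_mm
    L = mesh.cube_edge_mm
    f = np.zeros(mesh.n_nodes * 3)
    if load.p_max == 0.0:
        return f

    # elements in the top layer (ey = n-1)
    g = mesh.element_grid_indices()
    top_elems = np.flatnonzero(g[:, 1] == n - 1)
    conn = mesh.element_connectivity[top_elems][:, _TOP_FACE_LOCAL]  # (nf, 4)
    # facet corner coordinates in (x, z); bilinear shape functions on the facet
    x0 = mesh.node_coordinates[conn[:, 0], 0]
    z0 = mesh.node_coordinates[conn[:, 0], 2]
    # local facet node order [3, 2, 7, 6] -> (x, z) offsets (0,0),(1,0),(0,1),(1,1)
    facet_signs = np.array([(-1, -1), (1, -1), (-1, 1), (1, 1)], dtype=float)
    dA = (h / 2.0) ** 2
    for gx in (-_GAUSS, _GAUSS):
        for gz in (-_GAUSS, _GAUSS):
            N = (1 + gx * facet_signs[:, 0]) * (1 + gz * facet_signs[:, 1]) / 4.0
            x = x0 + h * (gx + 1) / 2.0
            p = load.pressure(x, L)
            contrib = p[:, None] * N[None, :] * dA  # (nf, 4)
            np.add.at(f, conn * 3 + 1, -contrib)
    return f


class CubeElasticityModel:
    """Reusable elasticity model: assembly indices, loads and constraints.

    Building one of these per mesh amortizes everything that does not
    depend on the modulus field; :meth:`solve` only rebuilds the matrix
    values and refactorizes.
    """

    def __init__(self, mesh: GridMesh, poisson: float, load: LoadCase):
        self.mesh = mesh
        self.poisson = float(poisson)
        self.load = load
        self.k_unit = _unit_element_stiffness(float(mesh.element_edge_mm), self.poisson)

        conn = mesh.element_connectivity
        dofs = (conn[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(-1, 24)
        self._rows = np.repeat(dofs, 24, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 24)).ravel()
        self.n_dofs = mesh.n_nodes * 3

        self.forces = consistent_surface_loads(mesh, load)
        self.fixed_dofs = self._fixed_dofs()
        free = np.ones(self.n_dofs, dtype=bool)
        free[self.fixed_dofs] = False
        self.free_dofs = np.flatnonzero(free)

    def _fixed_dofs(self) -> np.ndarray:
        mesh = self.mesh
        bottom = mesh.node_sets["BOTTOM_FACE"]
        fixed = set((bottom * 3 + 1).tolist())  # vertical on the bottom face
        # rigid-body pins: x, z at corner (0,0,0); z at corner (L,0,0)
        origin = 0
        corner_x = mesh.n_elements_per_axis  # node (L, 0, 0)
        fixed.update([origin * 3, origin * 3 + 2, corner_x * 3 + 2])
        return np.array(sorted(fixed), dtype=np.int64)

    def assemble(self, moduli: np.ndarray) -> sp.csr_matrix:
        """Global stiffness matrix for a per-element modulus field (MPa)."""
        data = (self.k_unit.ravel()[None, :] * np.asarray(moduli)[:, None]).ravel()
        K = sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self.n_dofs, self.n_dofs)
        )
        return K.tocsr()

    def solve(self, moduli: np.ndarray) -> FemSolution:
        moduli = np.asarray(moduli, dtype=float)
        if moduli.shape != (self.mesh.n_elements,):
            raise ValueError("moduli must be a per-element array")
        if not np.all(np.isfinite(moduli)) or np.any(moduli <= 0):
            raise ValueError("moduli must be positive and finite")

        zeros = np.zeros((self.mesh.n_nodes, 3))
        if self.load.p_max == 0.0:
            return FemSolution(zeros, np.zeros(self.mesh.n_elements), "OK", 0.0)

        K = self.assemble(moduli)
        free = self.free_dofs
        K_ff = K[free][:, free].tocsc()
        f_f = self.forces[free]
        try:
            lu = splu(K_ff)
            u_f = lu.solve(f_f)
        except (RuntimeError, ValueError) as exc:
            return FemSolution(
                zeros,
                np.zeros(self.mesh.n_elements),
                "UNSOLVABLE",
                np.inf,
                f"sparse factorization failed: {exc}",
            )

        u = np.zeros(self.n_dofs)
        u[free] = u_f
        if not np.all(np.isfinite(u)):
            return FemSolution(
                zeros,
                np.zeros(self.mesh.n_elements),
                "UNSOLVABLE",
                np.inf,
                "non-finite displacement solution",
            )

        residual = K @ u - self.forces
        fnorm = np.linalg.norm(self.forces)
        rel = np.linalg.norm(residual[free]) / fnorm
        disp = u.reshape(-1, 3)
        if rel > UNSOLVABLE_RESIDUAL:
            return FemSolution(
                disp,
                np.zeros(self.mesh.n_elements),
                "UNSOLVABLE",
                rel,
                f"equilibrium residual {rel:.3e} above {UNSOLVABLE_RESIDUAL:.0e}",
            )

        sed = element_sed(self.mesh, disp, moduli, self.poisson)
        return FemSolution(disp, sed, "OK", rel)

    def reaction_balance(self, moduli: np.ndarray, solution: FemSolution) -> float:
        """|sum of vertical reactions - applied load| / applied load."""
        K = self.assemble(np.asarray(moduli, dtype=float))
        r = K @ solution.displacements.ravel() - self.forces
        total_load = -self.forces[1::3].sum()  # positive downward magnitude
        reactions_y = r[self.fixed_dofs[self.fixed_dofs % 3 == 1]].sum()
        return abs(reactions_y - total_load) / abs(total_load)


def assemble_and_solve(
    mesh: GridMesh, moduli: np.ndarray, poisson: float, load: LoadCase
) -> FemSolution:
    """One-shot elasticity solve (builds a throwaway model)."""
    return CubeElasticityModel(mesh, poisson, load).solve(moduli)


def element_sed(
    mesh: GridMesh, displacements: np.ndarray, moduli: np.ndarray, poisson: float
) -> np.ndarray:
    """Apparent strain energy density per element, MPa = J/cm^3.

    The strain tensor is evaluated from the trilinear interpolation at the
    element centroid (the single centroid integration point), then
    U_a = 1/2 * strain : stress with the element's own modulus.
    """
    h = mesh.element_edge_mm
    # centroid shape gradients: dN_i/dx_c = sign[i, c] / (4h)
    G = _SIGNS.T / (4.0 * h)  # (3, 8)
    u_e = displacements[mesh.element_connectivity]  # (ne, 8, 3)
    grad = np.einsum("ci,eia->eac", G, u_e)  # (ne, 3, 3), du_a/dx_c
    exx = grad[:, 0, 0]
    eyy = grad[:, 1, 1]
    ezz = grad[:, 2, 2]
    gxy = grad[:, 0, 1] + grad[:, 1, 0]
    gyz = grad[:, 1, 2] + grad[:, 2, 1]
    gzx = grad[:, 2, 0] + grad[:, 0, 2]
    strain = np.stack([exx, eyy, ezz, gxy, gyz, gzx], axis=1)  # (ne, 6)
    C1 = isotropic_elasticity_matrix(1.0, poisson)
    sed_unit = 0.5 * np.einsum("ei,ij,ej->e", strain, C1, strain)
    sed = np.asarray(moduli, dtype=float) * sed_unit
    return np.maximum(sed, 0.0)
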