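"""Small-strain linear-elastic FEM on 4-node tetrahedra.

The disc tissue is treated as homogeneous, isotropic and linear elastic
(Hooke's law) with separate Young's modulus / Poisson ratio for the nucleus
pulposus and the annulus fibrosus.  Elements are constant-strain tets; the
global system uses a consistent mm-N-MPa unit system and is solved by direct
sparse factorization after eliminating the fixed degrees of freedom.

Loading model: the contact force on the disc's superior surface is the
component of the supported body weight along the surface normal,
``F = G * cos(alpha)``, where ``alpha`` is the proximal junctional angle
(PJA) and ``G`` the gravity load of the body mass above the UIV.  The force
acts along ``-z`` and is lumped over the superior-face nodes in proportion
to tributary area (consistent lumping of a uniform traction).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import TetMesh

__all__ = [
    "STANDARD_GRAVITY",
    "MaterialParams",
    "LoadCase",
    "FemSolution",
    "body_weight_to_G",
    "compute_loading_force",
    "elasticity_matrix",
    "element_stiffness",
    "von_mises",
    "assemble_and_solve",
]

#: m/s^2; weight in kg times this gives newtons.
STANDARD_GRAVITY = 9.81


@dataclasses.dataclass(frozen=True)
class MaterialParams:
    """Per-component isotropic elastic constants.

    ``young_modulus`` is in MPa; ``poisson_ratio`` dimensionless with
    ``0 <= nu < 0.5``.  Keys are the mesh component names.
    """

    young_modulus: Mapping[str, float]
    poisson_ratio: Mapping[str, float]

    def __post_init__(self) -> None:
        for comp, E in self.young_modulus.items():
            if not E > 0:
                raise ValueError(f"Young's modulus of {comp!r} must be > 0, got {E!r}")
        for comp, nu in self.poisson_ratio.items():
            if not 0.0 <= nu < 0.5:
                raise ValueError(f"Poisson ratio of {comp!r} must lie in [0, 0.5), got {nu!r}")

    @classmethod
    def disc_defaults(cls) -> "MaterialParams":
        """Literature values for the two disc components.

        Nucleus pulposus E = 1.0 MPa, nu = 0.49 (nearly incompressible gel);
        annulus fibrosus E = 3.4 MPa, nu = 0.45.
        """
        return cls(
            young_modulus={"annulus": 3.4, "nucleus": 1.0},
            poisson_ratio={"annulus": 0.45, "nucleus": 0.49},
        )


@dataclasses.dataclass(frozen=True)
class LoadCase:
    """One loading configuration of the disc.

    ``gravity_force_G`` is the weight (N) of the body above the UIV;
    ``pja_alpha_deg`` the proximal junctional angle in degrees.  The load
    direction is fixed along ``-z`` (normal to the superior face); only the
    magnitude ``G * cos(alpha)`` depends on the angle.
    """

    gravity_force_G: float
    pja_alpha_deg: float

    def __post_init__(self) -> None:
        if self.gravity_force_G < 0:
            raise ValueError(f"G must be >= 0, got {self.gravity_force_G!r}")
        if not 0.0 <= self.pja_alpha_deg < 90.0:
            raise ValueError(f"PJA must lie in [0, 90) degrees, got {self.pja_alpha_deg!r}")

    @property
    def force(self) -> float:
        return compute_loading_force(self.gravity_force_G, self.pja_alpha_deg)


@dataclasses.dataclass
class FemSolution:
    """Displacements and recovered stresses for one load case."""

    displacements: np.ndarray  #: (n_nodes, 3), mm
    stress_tensor: np.ndarray  #: (n_elements, 3, 3), MPa
    von_mises: np.ndarray  #: (n_elements,), MPa
    reactions: np.ndarray  #: (n_nodes, 3), N; nonzero only on fixed nodes
    applied_force: float  #: total load magnitude, N


def body_weight_to_G(weight_kg: float, uiv_fraction: float = 0.5) -> float:
    """Gravity load (N) carried by the disc: weight * g * fraction above UIV.

    ``uiv_fraction`` is the fraction of body mass supported above the upper
    instrumented vertebra; the default 0.5 is an anthropometric mid-thoracic
    stand-in and can be overridden per UIV level in the run configuration.
    """
    if not weight_kg > 0:
        raise ValueError(f"body weight must be > 0, got {weight_kg!r}")
    if not 0.0 < uiv_fraction <= 1.0:
        raise ValueError(f"uiv_fraction must lie in (0, 1], got {uiv_fraction!r}")
    return weight_kg * STANDARD_GRAVITY * uiv_fraction


def compute_loading_force(G: float, alpha_deg: float) -> float:
    """Axial contact force F = G * cos(alpha) on the disc surface, N."""
    if G < 0:
        raise ValueError(f"G must be >= 0, got {G!r}")
    if not 0.0 <= alpha_deg < 90.0:
        raise ValueError(f"alpha must lie in [0, 90) degrees, got {alpha_deg!r}")
    return float(G * np.cos(np.deg2rad(alpha_deg)))


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] += 2.0 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


def _shape_gradients(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Gradients of the 4 linear shape functions and the tet volume."""
    M = np.hstack([np.ones((4, 1)), coords])
    vol = np.linalg.det(M) / 6.0
    if vol <= 0:
        raise ValueError(f"degenerate or inverted tetrahedron (volume {vol:g})")
    grads = np.linalg.inv(M)[1:4, :].T  # (4, 3): grad of N_i
    return grads, vol


def _strain_displacement(grads: np.ndarray) -> np.ndarray:
    """6x12 B matrix (engineering shear) for a constant-strain tet."""
    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c], B[3, c + 1] = gy, gx
        B[4, c + 1], B[4, c + 2] = gz, gy
        B[5, c], B[5, c + 2] = gz, gx
    return B


def element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of one constant-strain tet: ``V * B^T D B``.

    Symmetric with exactly six zero-energy (rigid-body) modes.
    """
    grads, vol = _shape_gradients(np.asarray(coords, dtype=float))
    B = _strain_displacement(grads)
    D = elasticity_matrix(E, nu)
    return vol * B.T @ D @ B


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of symmetric 3x3 tensors (any batch shape)."""
    stress = np.asarray(stress, dtype=float)
    tr = np.trace(stress, axis1=-2, axis2=-1)
    dev = stress - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def _superior_tributary_areas(mesh: TetMesh) -> np.ndarray:
    """Per-node tributary area on the superior face (one third of each
    adjacent boundary triangle)."""
    sup = set(int(i) for i in mesh.superior_nodes)
    areas = np.zeros(mesh.n_nodes)
    faces = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))
    for tet in mesh.tets:
        for f in faces:
            tri = tet[list(f)]
            if all(int(n) in sup for n in tri):
                p0, p1, p2 = mesh.nodes[tri]
                area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0))
                areas[tri] += area / 3.0
    return areas


def assemble_and_solve(
    mesh: TetMesh, materials: MaterialParams, load: LoadCase
) -> FemSolution:
    """Assemble, apply boundary conditions, solve, and recover stresses.

    All inferior-face nodes are fixed in all three DOFs; the total force
    ``G * cos(alpha)`` is applied along ``-z`` over the superior-face nodes
    with tributary-area weights.  Constraints are handled by reduction to
    the free DOFs (exact satisfaction); the reduced SPD system is solved by
    direct sparse factorization.

    Raises
    ------
    ValueError
        If the mesh has no constrained nodes (singular system) or a
        component lacks material constants.
    """
    if mesh.inferior_nodes.size == 0:
        raise ValueError("no fixed nodes: the system would be singular "
                         "(mesh lacks an inferior boundary set)")
    for comp in np.unique(mesh.component_of_element):
        if comp not in materials.young_modulus or comp not in materials.poisson_ratio:
            raise ValueError(f"no material constants for component {comp!r}")

    n_dof = 3 * mesh.n_nodes
    n_el = mesh.n_elements

    D_by_comp = {
        comp: elasticity_matrix(materials.young_modulus[comp], materials.poisson_ratio[comp])
        for comp in np.unique(mesh.component_of_element)
    }

    B_all = np.empty((n_el, 6, 12))
    rows = np.empty(n_el * 144, dtype=np.int64)
    cols = np.empty(n_el * 144, dtype=np.int64)
    vals = np.empty(n_el * 144)
    for e in range(n_el):
        tet = mesh.tets[e]
        grads, vol = _shape_gradients(mesh.nodes[tet])
        B = _strain_displacement(grads)
        B_all[e] = B
        Ke = vol * B.T @ D_by_comp[mesh.component_of_element[e]] @ B
        dof = (3 * tet[:, None] + np.arange(3)[None, :]).ravel()
        rows[e * 144:(e + 1) * 144] = np.repeat(dof, 12)
        cols[e * 144:(e + 1) * 144] = np.tile(dof, 12)
        vals[e * 144:(e + 1) * 144] = Ke.ravel()
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    # uniform-traction load over the superior face, lumped by tributary area
    areas = _superior_tributary_areas(mesh)
    total_area = areas.sum()
    if total_area <= 0:
        raise ValueError("superior face has zero area; cannot apply the load")
    F = load.force
    f = np.zeros(n_dof)
    f[2::3] = -F * areas / total_area

    fixed = np.zeros(n_dof, dtype=bool)
    fixed[3 * mesh.inferior_nodes[:, None] + np.arange(3)] = True
    free = ~fixed

    u = np.zeros(n_dof)
    u[free] = spla.spsolve(K[free][:, free].tocsc(), f[free])

    residual = K @ u - f
    reactions = np.zeros(n_dof)
    reactions[fixed] = residual[fixed]

    # constant-strain stress recovery per element
    stress_voigt = np.empty((n_el, 6))
    for e in range(n_el):
        dof = (3 * mesh.tets[e][:, None] + np.arange(3)[None, :]).ravel()
        strain = B_all[e] @ u[dof]
        stress_voigt[e] = D_by_comp[mesh.component_of_element[e]] @ strain

    tensors = np.empty((n_el, 3, 3))
    xx, yy, zz, xy, yz, zx = stress_voigt.T
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = xx, yy, zz
    tensors[:, 0, 1] = tensors[:, 1, 0] = xy
    tensors[:, 1, 2] = tensors[:, 2, 1] = yz
    tensors[:, 0, 2] = tensors[:, 2, 0] = zx

    return FemSolution(
        displacements=u.reshape(-1, 3),
        stress_tensor=tensors,
        von_mises=von_mises(tensors),
        reactions=reactions.reshape(-1, 3),
        applied_force=F,
    )
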