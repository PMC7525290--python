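"""Parametric tetrahedral meshing of an idealized intervertebral disc.

The disc that sits immediately cephalad to the upper instrumented vertebra
(UIV) is modelled as an elliptic cylinder with two material components: an
inner nucleus pulposus bounded by a scaled-down copy of the outer ellipse,
and the surrounding annulus fibrosus.

Coordinate convention (fixed throughout the package):

* ``+x`` — patient left
* ``+y`` — anterior
* ``+z`` — cephalad

with the origin at the centroid of the inferior face.  This makes the
anterior/posterior and left/right subregion splits pure sign tests on
element centroids.

The mesh is built from a structured scaffold: the elliptic cross-section is
triangulated (a fan around the centre plus ring quads split into triangles),
each triangle is extruded through the axial layers into a prism, and each
prism is split into three tetrahedra using the smallest-global-vertex rule
for quad-face diagonals.  That rule assigns every interior quad face a
diagonal that both neighbouring prisms agree on, so the mesh is conforming,
and the construction is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np

__all__ = [
    "COMPONENTS",
    "SUBREGIONS",
    "DiscGeometryParams",
    "TetMesh",
    "build_disc_mesh",
    "label_subregions",
]

COMPONENTS = ("annulus", "nucleus")

#: The eight anatomical subregions: component (F = annulus fibrosus,
#: N = nucleus) x anterior/posterior x left/right, in fixed order.
SUBREGIONS = (
    "F-A-L", "F-A-R", "F-P-L", "F-P-R",
    "N-A-L", "N-A-R", "N-P-L", "N-P-R",
)

_COMPONENT_CODE = {"annulus": "F", "nucleus": "N"}


@dataclasses.dataclass(frozen=True)
class DiscGeometryParams:
    """Dimensions and resolution of the idealized disc.

    Parameters
    ----------
    lateral_radius : float
        Semi-axis of the outer ellipse along ``x`` (left-right), mm.
    ap_radius : float
        Semi-axis along ``y`` (anterior-posterior), mm.
    height : float
        Disc height along ``z``, mm.
    nucleus_scale : float
        Fraction in (0, 1) scaling the outer ellipse down to the
        nucleus/annulus interface.
    nucleus_offset_x, nucleus_offset_y : float
        In-plane offset (mm) of the nucleus centre from the disc axis.
        Real nuclei are rarely centred, and in scoliotic discs the offset
        is a natural source of left/right and anterior/posterior asymmetry.
        The offset nucleus ellipse must remain inside the outer ellipse.
    n_radial, n_circumferential, n_axial : int
        Structured-mesh resolutions (rings, sectors, layers), each >= 2.
    """

    lateral_radius: float = 20.0
    ap_radius: float = 14.0
    height: float = 8.0
    nucleus_scale: float = 0.6
    nucleus_offset_x: float = 0.0
    nucleus_offset_y: float = 0.0
    n_radial: int = 5
    n_circumferential: int = 16
    n_axial: int = 4

    def __post_init__(self) -> None:
        for name in ("lateral_radius", "ap_radius", "height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not 0.0 < self.nucleus_scale < 1.0:
            raise ValueError(f"nucleus_scale must lie in (0, 1), got {self.nucleus_scale!r}")
        slack_x = self.lateral_radius * (1.0 - self.nucleus_scale)
        slack_y = self.ap_radius * (1.0 - self.nucleus_scale)
        if (self.nucleus_offset_x / slack_x) ** 2 + (self.nucleus_offset_y / slack_y) ** 2 > 1.0:
            raise ValueError("nucleus offset pushes the nucleus outside the annulus")
        for name in ("n_radial", "n_circumferential", "n_axial"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 2):
                raise ValueError(f"{name} must be an integer >= 2, got {value!r}")

    @property
    def analytic_volume(self) -> float:
        """Exact volume of the continuous elliptic cylinder, mm^3."""
        return float(np.pi * self.lateral_radius * self.ap_radius * self.height)


@dataclasses.dataclass
class TetMesh:
    """A labelled 4-node tetrahedral mesh.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array
        Node coordinates, mm.
    tets : (n_elements, 4) int array
        Node indices per element, ordered so every signed volume is positive.
    component_of_element : (n_elements,) str array
        ``"annulus"`` or ``"nucleus"`` per element.
    subregion_of_element : (n_elements,) str array
        One of the eight :data:`SUBREGIONS` labels per element.
    inferior_nodes, superior_nodes : int arrays
        Node sets on the bottom (z = 0) and top (z = height) faces.
    """

    nodes: np.ndarray
    tets: np.ndarray
    component_of_element: np.ndarray
    subregion_of_element: np.ndarray
    inferior_nodes: np.ndarray
    superior_nodes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.tets.shape[0])

    def element_volumes(self) -> np.ndarray:
        """Signed volume of each tetrahedron (positive for a valid mesh)."""
        return _signed_volumes(self.nodes, self.tets)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def geometry_id(self) -> str:
        """Stable hash of node coordinates and connectivity.

        Used to reject stress-difference computations across mismatched
        geometries.
        """
        digest = hashlib.sha256()
        digest.update(np.ascontiguousarray(self.nodes, dtype=np.float64).tobytes())
        digest.update(np.ascontiguousarray(self.tets, dtype=np.int64).tobytes())
        return digest.hexdigest()[:16]


def _signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def _cross_section(params: DiscGeometryParams) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the elliptic cross-section.

    Returns 2-D points and a (T, 3) triangle array.  Node 0 is the centre;
    ring ``i`` (1-based) holds ``n_circumferential`` nodes at radius fraction
    ``i / n_radial``.
    """
    nr, nc = params.n_radial, params.n_circumferential
    a, b = params.lateral_radius, params.ap_radius

    theta = 2.0 * np.pi * np.arange(nc) / nc
    pts = [np.zeros((1, 2))]
    for i in range(1, nr + 1):
        frac = i / nr
        pts.append(np.column_stack([a * frac * np.cos(theta), b * frac * np.sin(theta)]))
    pts2d = np.vstack(pts)

    def ring(i: int, j: int) -> int:
        return 1 + (i - 1) * nc + (j % nc)

    tris = []
    for j in range(nc):  # centre fan
        tris.append((0, ring(1, j), ring(1, j + 1)))
    for i in range(1, nr):  # ring quads, fixed diagonal
        for j in range(nc):
            q00, q10 = ring(i, j), ring(i + 1, j)
            q11, q01 = ring(i + 1, j + 1), ring(i, j + 1)
            tris.append((q00, q10, q11))
            tris.append((q00, q11, q01))
    return pts2d, np.asarray(tris, dtype=np.int64)


def _prism_to_tets(v: list[int]) -> list[tuple[int, int, int, int]]:
    """Split a triangular prism into 3 tets honouring min-vertex diagonals.

    ``v`` holds global node indices: bottom triangle ``v[0:3]``, top triangle
    ``v[3:6]`` with ``v[i+3]`` above ``v[i]``.  Each quad face receives the
    diagonal through its smallest global index, so the split of a shared face
    is identical in both adjacent prisms.
    """
    idx = int(np.argmin(v))
    if idx >= 3:  # rotate so the smallest vertex sits on the bottom triangle
        v = [v[3], v[4], v[5], v[0], v[1], v[2]]
        idx -= 3
    order = (idx, (idx + 1) % 3, (idx + 2) % 3)
    v0, v1, v2 = (v[o] for o in order)
    v3, v4, v5 = (v[o + 3] for o in order)
    # faces through v0 take diagonals (v0, v4) and (v0, v5); third face by min
    if min(v1, v5) < min(v2, v4):
        return [(v0, v1, v2, v5), (v0, v1, v5, v4), (v0, v4, v5, v3)]
    return [(v0, v1, v2, v4), (v0, v4, v2, v5), (v0, v4, v5, v3)]


def build_disc_mesh(params: DiscGeometryParams | None = None) -> TetMesh:
    """Build a conforming, fully labelled tet mesh of the idealized disc.

    Elements whose centroid lies inside the inner ellipse (outer semi-axes
    scaled by ``nucleus_scale``) are labelled ``nucleus``, the rest
    ``annulus``; subregions are then assigned via :func:`label_subregions`.
    Bottom-face nodes form ``inferior_nodes`` and top-face nodes
    ``superior_nodes``.

    Raises
    ------
    ValueError
        If the parameters are degenerate or the construction produces a
        non-positive element volume (never expected for valid parameters).
    """
    if params is None:
        params = DiscGeometryParams()

    pts2d, tris = _cross_section(params)
    n2d = pts2d.shape[0]
    na = params.n_axial
    z_levels = np.linspace(0.0, params.height, na + 1)

    nodes = np.empty((n2d * (na + 1), 3))
    for k, z in enumerate(z_levels):
        nodes[k * n2d:(k + 1) * n2d, :2] = pts2d
        nodes[k * n2d:(k + 1) * n2d, 2] = z

    tets: list[tuple[int, int, int, int]] = []
    for k in range(na):
        lo, hi = k * n2d, (k + 1) * n2d
        for p, q, r in tris:
            tets.extend(_prism_to_tets([lo + p, lo + q, lo + r, hi + p, hi + q, hi + r]))
    tet_arr = np.asarray(tets, dtype=np.int64)

    # enforce positive orientation (node-set preserving, so still conforming)
    vols = _signed_volumes(nodes, tet_arr)
    flip = vols < 0
    tet_arr[flip, 2], tet_arr[flip, 3] = tet_arr[flip, 3], tet_arr[flip, 2].copy()
    vols = np.abs(vols)
    if np.any(vols <= 1e-12 * params.analytic_volume / max(len(tet_arr), 1)):
        raise ValueError("mesh construction produced a degenerate element")

    centroids = nodes[tet_arr].mean(axis=1)
    r2 = (
        (centroids[:, 0] - params.nucleus_offset_x)
        / (params.lateral_radius * params.nucleus_scale)
    ) ** 2 + (
        (centroids[:, 1] - params.nucleus_offset_y)
        / (params.ap_radius * params.nucleus_scale)
    ) ** 2
    component = np.where(r2 <= 1.0, "nucleus", "annulus").astype("<U7")

    inferior = np.flatnonzero(nodes[:, 2] == 0.0)
    superior = np.flatnonzero(nodes[:, 2] == params.height)

    mesh = TetMesh(
        nodes=nodes,
        tets=tet_arr,
        component_of_element=component,
        subregion_of_element=np.empty(len(tet_arr), dtype="<U5"),
        inferior_nodes=inferior,
        superior_nodes=superior,
    )
    return label_subregions(mesh)


def label_subregions(mesh: TetMesh) -> TetMesh:
    """Assign each element one of the eight anatomical subregion labels.

    The label combines the element's material component (F/N) with sign
    tests on its centroid: anterior if ``y >= 0`` else posterior, left if
    ``x >= 0`` else right.  Centroids exactly on a dividing plane go to the
    non-negative side (deterministic tie-break).
    """
    if mesh.component_of_element.shape[0] != mesh.n_elements:
        raise ValueError("mesh must carry component labels before subregion labelling")
    centroids = mesh.element_centroids()
    comp = np.array([_COMPONENT_CODE[c] for c in mesh.component_of_element])
    ap = np.where(centroids[:, 1] >= 0.0, "A", "P")
    lr = np.where(centroids[:, 0] >= 0.0, "L", "R")
    labels = np.array([f"{c}-{s}-{h}" for c, s, h in zip(comp, ap, lr)], dtype="<U5")
    return dataclasses.replace(mesh, subregion_of_element=labels)
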