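"""Surface and tetrahedral mesh construction for bead geometries.

Surfaces are triangulated in physical micrometre coordinates, either
generated analytically (icospheres for the undeformed reference bead) or
extracted from segmented confocal label stacks by marching cubes on an
isotropically resampled volume.  Closed surfaces are tetrahedralized by a
Delaunay triangulation of the surface vertices plus an interior point
lattice; meshes can be promoted from 4-node to 10-node (quadratic)
tetrahedra with optional projection of boundary midside nodes onto a
curved surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import Delaunay
from skimage import measure

from . import _surfquery

__all__ = [
    "TriSurfaceMesh",
    "TetMesh",
    "GeometryError",
    "make_sphere_surface",
    "surface_from_labels",
    "tetrahedralize",
    "mesh_volume",
    "boundary_volume",
    "promote_to_quadratic",
]


class GeometryError(ValueError):
    """Raised for invalid geometry (open surfaces, inverted elements, ...)."""


# ---------------------------------------------------------------------------
# surface meshes
# ---------------------------------------------------------------------------


@dataclass
class TriSurfaceMesh:
    """Closed, outward-oriented triangulated surface in micrometres."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3)")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriSurfaceMesh":
        return cls(np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64))

    def validate_closed(self) -> trimesh.Trimesh:
        """Return the trimesh view, raising unless closed and consistently wound."""
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise GeometryError("surface is not closed (open edges present)")
        if not tm.is_winding_consistent:
            raise GeometryError("surface winding is inconsistent")
        if tm.volume < 0:
            tm.invert()
        return tm

    @property
    def enclosed_volume(self) -> float:
        """Signed enclosed volume, µm³ (positive for outward orientation)."""
        return float(abs(self.to_trimesh().volume))


def make_sphere_surface(radius: float, refinement: int = 3) -> TriSurfaceMesh:
    """Icosphere with ``20 * 4**refinement`` faces; vertices exactly at ``radius``."""
    if not radius > 0:
        raise GeometryError(f"radius must be positive, got {radius}")
    if refinement < 0:
        raise GeometryError("refinement must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=refinement, radius=1.0)
    verts = np.asarray(ico.vertices, float)
    # re-normalize so every vertex norm equals the radius to machine precision
    verts = radius * verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return TriSurfaceMesh(verts, np.asarray(ico.faces, np.int64))


def surface_from_labels(
    labels,
    smoothing_iterations: int = 10,
    voxel_size: float | None = None,
) -> TriSurfaceMesh:
    """Triangulated surface of a segmented bead.

    The binary label stack (a :class:`~compax.imaging.LabelStack`) is
    box-filtered and resampled onto an isotropic grid of spacing
    ``voxel_size`` (µm, default: the z spacing), so in-plane detail is
    turned into partial-volume values rather than aliased away; the 0.5
    isosurface is then extracted by marching cubes and regularized by
    Taubin smoothing, followed by a uniform rescale about the centroid
    that restores the pre-smoothing enclosed volume (the volume is the
    physically meaningful quantity downstream).  Coordinates are physical
    micrometres with the origin at the corner of the original stack.

    Raises
    ------
    GeometryError
        If the foreground touches the stack border (the bead must be
        fully imaged) or spans fewer than 3 slices.
    """
    mask = np.asarray(labels.labels).astype(bool)
    if mask.sum() == 0:
        raise GeometryError("label stack is empty")
    zs = np.where(mask.any(axis=(1, 2)))[0]
    if zs.size < 3:
        raise GeometryError("foreground must span at least 3 slices")
    border = (
        mask[0].any()
        or mask[-1].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
        or mask[:, :, 0].any()
        or mask[:, :, -1].any()
    )
    if border:
        raise GeometryError("foreground touches the stack border; bead not fully imaged")

    # stack axes are (z, y, x); physical spacings (z, xy, xy)
    spacing = np.array([labels.spacing_z, labels.spacing_xy, labels.spacing_xy])
    if voxel_size is None:
        voxel_size = float(labels.spacing_z)
    zoom = spacing / voxel_size
    # box-filter where downsampling so fine in-plane voxels become
    # partial-volume values (sub-voxel interface localization)
    size_vox = np.maximum(1, np.round(1.0 / zoom)).astype(int)
    f = ndimage.uniform_filter(mask.astype(np.float64), size=tuple(size_vox))
    vol = ndimage.zoom(f, zoom, order=1, grid_mode=True, mode="grid-constant")
    vol = np.pad(vol, 1, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5)
    verts = (verts - 1.0) * voxel_size  # undo padding, to physical units

    tm = trimesh.Trimesh(verts, faces, process=True)
    # keep the largest closed component
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: abs(p.volume))
    if not tm.is_watertight:
        raise GeometryError("isosurface is not closed")
    if tm.volume < 0:
        tm.invert()
    if smoothing_iterations > 0:
        v_pre = abs(tm.volume)
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=-0.53,
                                        iterations=smoothing_iterations)
        c = tm.centroid.copy()
        tm.vertices = c + (tm.vertices - c) * (v_pre / abs(tm.volume)) ** (1.0 / 3.0)
    # back to (x, y, z) ordering: marching cubes worked on (z, y, x) axes
    verts = np.asarray(tm.vertices, float)[:, ::-1].copy()
    faces = np.asarray(tm.faces, np.int64)[:, ::-1].copy()  # flip winding with axis swap
    return TriSurfaceMesh(verts, faces)


# ---------------------------------------------------------------------------
# tetrahedral meshes
# ---------------------------------------------------------------------------

# local faces of a positively oriented tetrahedron, outward-wound
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
# edge numbering of the 10-node tetrahedron (VTK quadratic tetra convention)
TET10_EDGES = np.array([[0, 1], [1, 2], [2, 0], [0, 3], [1, 3], [2, 3]])


@dataclass
class TetMesh:
    """Tetrahedral mesh: 4-node (linear) or 10-node (quadratic) elements.

    ``nodes`` are micrometre coordinates; for quadratic elements the first
    four columns of ``elements`` are the corners, followed by the edge
    midside nodes in VTK order.
    """

    nodes: np.ndarray
    elements: np.ndarray
    _boundary_faces: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.shape[1] not in (4, 10):
            raise GeometryError("elements must have 4 or 10 nodes")

    @property
    def order(self) -> int:
        return 1 if self.elements.shape[1] == 4 else 2

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def corner_volumes(self) -> np.ndarray:
        """Signed volumes from the corner nodes of each element."""
        x = self.nodes[self.elements[:, :4]]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented boundary faces, ``(k, 3)`` or ``(k, 6)``."""
        if self._boundary_faces is not None:
            return self._boundary_faces
        corners = self.elements[:, :4]
        faces = corners[:, _TET_FACES].reshape(-1, 3)  # (4*nel, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        bmask = counts[inv] == 1
        bfaces = faces[bmask]
        if self.order == 2:
            # attach midside nodes from the parent elements
            eidx = np.nonzero(bmask)[0] // 4
            lface = np.nonzero(bmask)[0] % 4
            mids = np.empty((bfaces.shape[0], 3), dtype=np.int64)
            edge_lookup = {}
            for k, (a, b) in enumerate(TET10_EDGES):
                edge_lookup[(a, b)] = 4 + k
                edge_lookup[(b, a)] = 4 + k
            for j in range(bfaces.shape[0]):
                el = self.elements[eidx[j]]
                lf = _TET_FACES[lface[j]]
                for m in range(3):
                    a, b = lf[m], lf[(m + 1) % 3]
                    mids[j, m] = el[edge_lookup[(a, b)]]
            bfaces = np.hstack([bfaces, mids])
        self._boundary_faces = bfaces
        return bfaces

    @property
    def surface_node_ids(self) -> np.ndarray:
        """Sorted ids of all nodes on the boundary (corners and midsides)."""
        return np.unique(self.boundary_faces())

    def volume_centroid(self) -> np.ndarray:
        """Volume-weighted centroid of the mesh, from corner-node volumes."""
        v = self.corner_volumes()
        c = self.nodes[self.elements[:, :4]].mean(axis=1)
        return (v[:, None] * c).sum(axis=0) / v.sum()

    def with_nodes(self, nodes: np.ndarray) -> "TetMesh":
        """Same connectivity on new node coordinates."""
        return TetMesh(np.asarray(nodes, float), self.elements)


# degree-3 5-point tetrahedron rule (exact for the quadratic isoparametric
# volume Jacobian); weights sum to 1/6
_TET5_PTS = np.array(
    [
        [0.25, 0.25, 0.25],
        [0.5, 1 / 6, 1 / 6],
        [1 / 6, 0.5, 1 / 6],
        [1 / 6, 1 / 6, 0.5],
        [1 / 6, 1 / 6, 1 / 6],
    ]
)
_TET5_WTS = np.array([-4.0 / 5.0, 9.0 / 20.0, 9.0 / 20.0, 9.0 / 20.0, 9.0 / 20.0]) / 6.0


def tet10_shape_gradients(points: np.ndarray) -> np.ndarray:
    """Gradients of the 10 quadratic shape functions w.r.t. (xi, eta, zeta).

    Returns an array of shape ``(npts, 10, 3)``.  Barycentric coordinates
    are ``l0 = 1 - xi - eta - zeta, l1 = xi, l2 = eta, l3 = zeta``.
    """
    pts = np.atleast_2d(points)
    n = pts.shape[0]
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    l0 = 1.0 - xi - eta - zeta
    lam = np.stack([l0, xi, eta, zeta], axis=1)  # (n, 4)
    # dl/dxi: l0 -> (-1,-1,-1), l1 -> (1,0,0), l2 -> (0,1,0), l3 -> (0,0,1)
    dlam = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    g = np.zeros((n, 10, 3))
    for c in range(4):  # corners: N = l(2l - 1)
        g[:, c, :] = (4.0 * lam[:, c, None] - 1.0) * dlam[c]
    for k, (a, b) in enumerate(TET10_EDGES):  # midsides: N = 4 la lb
        g[:, 4 + k, :] = 4.0 * (lam[:, a, None] * dlam[b] + lam[:, b, None] * dlam[a])
    return g


def tet10_shape_values(points: np.ndarray) -> np.ndarray:
    """Values of the 10 quadratic shape functions, shape ``(npts, 10)``."""
    pts = np.atleast_2d(points)
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    l0 = 1.0 - xi - eta - zeta
    lam = np.stack([l0, xi, eta, zeta], axis=1)
    vals = np.empty((pts.shape[0], 10))
    for c in range(4):
        vals[:, c] = lam[:, c] * (2.0 * lam[:, c] - 1.0)
    for k, (a, b) in enumerate(TET10_EDGES):
        vals[:, 4 + k] = 4.0 * lam[:, a] * lam[:, b]
    return vals


def mesh_volume(mesh: TetMesh) -> float:
    """Total mesh volume in µm³.

    Linear meshes use the exact signed-determinant formula; quadratic
    meshes integrate the isoparametric Jacobian with a degree-3 rule,
    which is exact for quadratic geometry.  Raises on inverted elements.
    """
    if mesh.order == 1:
        v = mesh.corner_volumes()
        bad = np.nonzero(v <= 0)[0]
        if bad.size:
            raise GeometryError(f"inverted element(s): ids {bad[:10].tolist()}")
        return float(v.sum())
    g = tet10_shape_gradients(_TET5_PTS)  # (5, 10, 3)
    x = mesh.nodes[mesh.elements]  # (nel, 10, 3)
    J = np.einsum("qai,eaj->eqij", g, x)  # (nel, 5, 3, 3)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = np.nonzero((detJ <= 0).any(axis=1))[0]
        raise GeometryError(f"inverted element(s): ids {bad[:10].tolist()}")
    return float(np.einsum("q,eq->", _TET5_WTS, detJ))


# 6-point degree-4 triangle rule (barycentric), weights sum to 1/2
_TRI6_A = 0.445948490915965
_TRI6_B = 0.091576213509771
_TRI6_PTS = np.array(
    [
        [_TRI6_A, _TRI6_A],
        [1 - 2 * _TRI6_A, _TRI6_A],
        [_TRI6_A, 1 - 2 * _TRI6_A],
        [_TRI6_B, _TRI6_B],
        [1 - 2 * _TRI6_B, _TRI6_B],
        [_TRI6_B, 1 - 2 * _TRI6_B],
    ]
)
_TRI6_WTS = np.array([0.111690794839005] * 3 + [0.054975871827661] * 3)


def tri6_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic triangle shape values and gradients.

    Node order: corners 0, 1, 2 then midsides (0,1), (1,2), (2,0).
    Returns ``(values (n, 6), gradients (n, 6, 2))``.
    """
    pts = np.atleast_2d(points)
    xi, eta = pts[:, 0], pts[:, 1]
    l0 = 1.0 - xi - eta
    lam = np.stack([l0, xi, eta], axis=1)
    dlam = np.array([[-1.0, -1.0], [1, 0], [0, 1]])
    edges = [(0, 1), (1, 2), (2, 0)]
    vals = np.empty((pts.shape[0], 6))
    grads = np.zeros((pts.shape[0], 6, 2))
    for c in range(3):
        vals[:, c] = lam[:, c] * (2 * lam[:, c] - 1)
        grads[:, c, :] = (4 * lam[:, c, None] - 1) * dlam[c]
    for k, (a, b) in enumerate(edges):
        vals[:, 3 + k] = 4 * lam[:, a] * lam[:, b]
        grads[:, 3 + k, :] = 4 * (lam[:, a, None] * dlam[b] + lam[:, b, None] * dlam[a])
    return vals, grads


def boundary_volume(mesh: TetMesh) -> float:
    """Enclosed volume from the divergence theorem over the boundary.

    ``V = (1/3) oint x . n dA`` integrated over the (possibly curved)
    boundary triangulation; exact for both linear and quadratic faces.
    """
    faces = mesh.boundary_faces()
    if mesh.order == 1:
        x = mesh.nodes[faces]  # (k, 3, 3)
        cross = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        return float(np.einsum("ki,ki->", x.mean(axis=1), cross) / 6.0)
    vals, grads = tri6_shape(_TRI6_PTS)
    x = mesh.nodes[faces]  # (k, 6, 3)
    xq = np.einsum("qa,kai->kqi", vals, x)
    dx = np.einsum("qam,kai->kqim", grads, x)  # (k, q, 3, 2)
    nvec = np.cross(dx[..., 0], dx[..., 1])
    return float(np.einsum("q,kqi,kqi->", _TRI6_WTS, xq, nvec) / 3.0)


def tetrahedralize(
    surface: TriSurfaceMesh,
    max_tet_volume: float | None = None,
    interior_margin: float = 0.45,
    jitter: float = 0.05,
) -> TetMesh:
    """Tetrahedralize the interior of a closed surface.

    A body-centred interior point lattice (spacing derived from
    ``max_tet_volume``; defaults to the mean surface edge length) is
    combined with the surface vertices and Delaunay-triangulated; tets
    whose centroid falls outside the surface are discarded.  Surface
    vertices are preserved exactly as mesh nodes.  Suited to convex and
    mildly non-convex (star-shaped) bead geometries.
    """
    tm = surface.validate_closed()

    edges = np.linalg.norm(
        tm.vertices[tm.edges_unique[:, 0]] - tm.vertices[tm.edges_unique[:, 1]], axis=1
    )
    if max_tet_volume is None:
        h = float(edges.mean())
    else:
        if not max_tet_volume > 0:
            raise GeometryError("max_tet_volume must be positive")
        h = float((6.0 * np.sqrt(2.0) * max_tet_volume) ** (1.0 / 3.0))

    lo, hi = tm.bounds
    axes = [np.arange(lo[i] + h / 2, hi[i], h) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # deterministic jitter breaks lattice degeneracies in the Delaunay step
    rng = np.random.RandomState(0)
    grid = grid + (jitter * h) * (rng.rand(*grid.shape) - 0.5)
    verts_f = np.asarray(tm.vertices, float)
    faces_f = np.asarray(tm.faces, np.int64)
    if grid.shape[0]:
        inside = _surfquery.contains(verts_f, faces_f, grid)
        grid = grid[inside]
        _, dist = _surfquery.closest_point(verts_f, faces_f, grid)
        interior = grid[dist > interior_margin * h]
    else:
        interior = np.empty((0, 3))
    if interior.shape[0] == 0:
        interior = tm.centroid[None, :]

    pts = np.vstack([surface.vertices, interior])
    tri = Delaunay(pts)
    tets = tri.simplices.astype(np.int64)

    cent = pts[tets].mean(axis=1)
    tets = tets[_surfquery.contains(verts_f, faces_f, cent)]

    # orient positively and drop degenerate slivers
    x = pts[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    flip = vol < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1], tets[flip, 0].copy()
    vol = np.abs(vol)
    tets = tets[vol > 1e-9 * h**3]
    if tets.shape[0] == 0:
        raise GeometryError("tetrahedralization produced no interior elements")

    # drop unreferenced points (interior lattice points that ended outside)
    used = np.unique(tets)
    remap = -np.ones(pts.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TetMesh(pts[used], remap[tets])


def promote_to_quadratic(mesh: TetMesh, project_boundary=None) -> TetMesh:
    """Promote a linear tet mesh to 10-node quadratic elements.

    Midside nodes are placed at edge midpoints; if ``project_boundary``
    is given (a callable mapping ``(k, 3)`` points to ``(k, 3)`` points),
    midside nodes of boundary edges are projected with it, producing
    curved isoparametric boundary elements.
    """
    if mesh.order == 2:
        return mesh
    elems = mesh.elements
    edge_pairs = elems[:, TET10_EDGES]  # (nel, 6, 2)
    flat = np.sort(edge_pairs.reshape(-1, 2), axis=1)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])

    if project_boundary is not None:
        bfaces = mesh.boundary_faces()
        bedges = np.sort(
            np.concatenate(
                [bfaces[:, [0, 1]], bfaces[:, [1, 2]], bfaces[:, [2, 0]]]
            ),
            axis=1,
        )
        bset = set(map(tuple, bedges.tolist()))
        is_b = np.fromiter(
            (tuple(e) in bset for e in uniq.tolist()), count=uniq.shape[0], dtype=bool
        )
        if is_b.any():
            mid[is_b] = project_boundary(mid[is_b])

    mid_ids = mesh.n_nodes + inv.reshape(elems.shape[0], 6)
    nodes = np.vstack([mesh.nodes, mid])
    elements = np.hstack([elems, mid_ids])
    return TetMesh(nodes, elements)


def sphere_projector(center: np.ndarray, radius: float):
    """Radial projection onto a sphere, for curved boundary midside nodes."""
    c = np.asarray(center, float)

    def project(p: np.ndarray) -> np.ndarray:
        d = p - c
        r = np.linalg.norm(d, axis=1, keepdims=True)
        return c + radius * d / r

    return project


def surface_projector(surface: TriSurfaceMesh):
    """Closest-point projection onto a triangulated surface."""
    verts = np.asarray(surface.vertices, float)
    faces = np.asarray(surface.faces, np.int64)

    def project(p: np.ndarray) -> np.ndarray:
        closest, _ = _surfquery.closest_point(verts, faces, p)
        return closest

    return project
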