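"""Three-step inverse stress reconstruction from a deformed bead shape.

Given only the deformed geometry of an elastic bead whose stress-free
shape is assumed to be a sphere of known diameter, the stress state is
recovered in three steps:

1. mesh the deformed bead (from a confocal stack, a binary label stack,
   or a surface mesh);
2. compute per-boundary-node *radial distance vectors* that map the
   deformed surface radially onto the assumed reference sphere, and apply
   them as Dirichlet data in a preprocessing solve whose deformed output
   mesh serves as the (assumed stress-free) reference configuration;
3. apply the *inverse* radial vectors as surface displacements to that
   reference mesh in the main solve; the resulting Cauchy stress field is
   the estimate of the stress state in the observed, deformed bead.

The construction is only defined for star-shaped deformed beads (every
boundary point visible from the reference center along its ray); violating
shapes raise an error rather than silently producing a multivalued map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .fem import DirichletBC, DisplacementField, StressField
from .geometry import (
    GeometryError,
    TetMesh,
    TriSurfaceMesh,
    promote_to_quadratic,
    surface_from_labels,
    surface_projector,
    tetrahedralize,
)
from .imaging import ImageStack, LabelStack, equivalent_diameter, segment_bead
from .material import Material
from .stress import StressSummary, summarize

__all__ = [
    "ReferenceSpec",
    "RadialVectors",
    "CompaxResult",
    "build_deformed_mesh",
    "radial_distance_vectors",
    "make_reference_mesh",
    "reconstruct",
    "approx_mean_pressure",
    "run_compax",
]


@dataclass
class ReferenceSpec:
    """Assumed stress-free reference: a sphere of known mean diameter.

    ``center=None`` uses the volume centroid of the deformed mesh, which
    is unique and equivariant under rigid motions of the observation.
    """

    diameter: float = 17.0
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if self.center is not None:
            self.center = np.asarray(self.center, float).reshape(3)


@dataclass
class RadialVectors:
    """Per-boundary-node vectors from the deformed surface to the sphere."""

    node_ids: np.ndarray
    vectors: np.ndarray
    center: np.ndarray
    diameter: float


def build_deformed_mesh(
    stack: ImageStack | LabelStack | TriSurfaceMesh,
    smoothing_iterations: int = 10,
    voxel_size: float | None = None,
    max_tet_volume: float | None = None,
    order: int = 2,
) -> TetMesh:
    """Tetrahedral mesh of the deformed bead.

    Accepts an intensity stack (segmented first), a binary label stack,
    or a ready triangulated surface; composition of segmentation,
    isosurface extraction and tetrahedralization.  Quadratic meshes get
    their boundary midside nodes projected onto the surface.
    """
    if isinstance(stack, TriSurfaceMesh):
        surface = stack
    else:
        labels = stack if isinstance(stack, LabelStack) else segment_bead(stack)
        surface = surface_from_labels(labels, smoothing_iterations, voxel_size)
    mesh = tetrahedralize(surface, max_tet_volume)
    if order == 2:
        mesh = promote_to_quadratic(mesh, surface_projector(surface))
    vol = surface.enclosed_volume
    _log_volume(vol)
    return mesh


def _log_volume(vol: float) -> None:
    import logging

    logging.getLogger(__name__).info(
        "deformed bead: volume %.1f um^3, equivalent diameter %.2f um",
        vol, equivalent_diameter(vol),
    )


def radial_distance_vectors(mesh: TetMesh, ref: ReferenceSpec) -> RadialVectors:
    """Vectors from each boundary node radially onto the reference sphere.

    ``v_i = (R - |x_i - c|) (x_i - c)/|x_i - c|`` with ``R`` the reference
    radius and ``c`` the center; positive magnitude points outward for
    nodes inside the sphere.
    """
    center = ref.center if ref.center is not None else mesh.volume_centroid()
    R = ref.diameter / 2.0
    ids = mesh.surface_node_ids
    d = mesh.nodes[ids] - center
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise GeometryError("boundary node coincides with the reference center")
    _check_star_shaped(mesh, center)
    vec = ((R - r) / r)[:, None] * d
    return RadialVectors(node_ids=ids, vectors=vec, center=np.asarray(center, float),
                         diameter=ref.diameter)


def _check_star_shaped(mesh: TetMesh, center: np.ndarray) -> None:
    """Every outward boundary-face normal must face away from the center."""
    faces = mesh.boundary_faces()[:, :3]
    x = mesh.nodes[faces]
    n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    mid = x.mean(axis=1) - center
    if np.any(np.einsum("ki,ki->k", n, mid) <= 0):
        raise GeometryError(
            "deformed surface is not star-shaped about the reference center; "
            "the radial construction is undefined"
        )


def make_reference_mesh(
    deformed: TetMesh,
    vectors: RadialVectors,
    material: Material,
    n_load_steps: int = 3,
    tol: float = 1e-8,
) -> TetMesh:
    """Preprocessing solve: map the deformed mesh onto the reference sphere.

    The radial vectors are applied as Dirichlet data; the displaced mesh
    (same connectivity) is returned and subsequently treated as the
    stress-free reference configuration.
    """
    if not np.array_equal(np.sort(vectors.node_ids), deformed.surface_node_ids):
        raise ValueError("vectors must cover exactly the boundary nodes")
    bc = DirichletBC(vectors.node_ids, vectors.vectors)
    try:
        fld = fem.solve_static(deformed, material, dirichlet=bc,
                               n_load_steps=n_load_steps, tol=tol)
    except fem.SolverError as err:
        raise fem.SolverError(
            f"preprocessing solve failed ({err}); try more load steps",
            err.last_converged_fraction,
        ) from err
    return deformed.with_nodes(deformed.nodes + fld.u)


@dataclass
class CompaxResult:
    """Everything the inverse reconstruction produces."""

    stress: StressField
    displacement: DisplacementField
    reference_mesh: TetMesh
    vectors: RadialVectors
    summary: StressSummary
    approx_pressure: float


def reconstruct(
    reference: TetMesh,
    vectors: RadialVectors,
    material: Material,
    n_load_steps: int = 3,
    tol: float = 1e-8,
) -> StressField:
    """Main solve: inverse radial vectors as surface displacements.

    Applied to the reference mesh produced by :func:`make_reference_mesh`
    with the same vectors, the prescribed boundary displacement returns
    every boundary node exactly to its observed (deformed) position; the
    returned field is the Cauchy stress of that deformed state.
    """
    bc = DirichletBC(vectors.node_ids, -vectors.vectors)
    fld = fem.solve_static(reference, material, dirichlet=bc,
                           n_load_steps=n_load_steps, tol=tol)
    return fem.cauchy_stress(reference, fld, material)


def approx_mean_pressure(V_c: float, V_r: float, kappa: float) -> float:
    """Small-strain mean-pressure estimate ``-kappa (V_c - V_r)/V_r`` (Pa).

    Positive = compression.  Exact only to first order in the volume
    change; at finite strain the volume average of the nonlinear local
    pressure differs from this bead-scale evaluation.
    """
    if not (V_c > 0 and V_r > 0):
        raise ValueError("volumes must be positive")
    return -kappa * (V_c - V_r) / V_r


def run_compax(
    deformed: TetMesh,
    material: Material,
    ref: ReferenceSpec | None = None,
    n_load_steps: int = 3,
    tol: float = 1e-8,
) -> CompaxResult:
    """Full inverse reconstruction from a deformed tetrahedral mesh."""
    ref = ref or ReferenceSpec()
    vectors = radial_distance_vectors(deformed, ref)
    reference = make_reference_mesh(deformed, vectors, material, n_load_steps, tol)
    bc = DirichletBC(vectors.node_ids, -vectors.vectors)
    fld = fem.solve_static(reference, material, dirichlet=bc,
                           n_load_steps=n_load_steps, tol=tol)
    stress = fem.cauchy_stress(reference, fld, material)
    from .geometry import mesh_volume

    V_r = mesh_volume(reference)
    summary = summarize(stress, V_r)
    return CompaxResult(
        stress=stress,
        displacement=fld,
        reference_mesh=reference,
        vectors=vectors,
        summary=summary,
        approx_pressure=approx_mean_pressure(summary.V_c, V_r, material.kappa),
    )
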