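"""Surface extraction, sphere meshing, tetrahedralization, volumes."""

import numpy as np
import pytest

from compax.geometry import (
    GeometryError,
    TetMesh,
    boundary_volume,
    make_sphere_surface,
    mesh_volume,
    promote_to_quadratic,
    sphere_projector,
    surface_from_labels,
    tetrahedralize,
)
from compax.imaging import LabelStack

from .test_imaging import sphere_labels

SPHERE_VOLUME = 4.0 / 3.0 * np.pi * 8.5**3


class TestIcosphere:
    def test_refinement_zero_is_icosahedron(self):
        s = make_sphere_surface(1.0, refinement=0)
        assert s.faces.shape == (20, 3)
        assert s.vertices.shape == (12, 3)

    @pytest.mark.parametrize("refinement", [0, 2])
    def test_vertex_norms_exact(self, refinement):
        s = make_sphere_surface(8.5, refinement)
        r = np.linalg.norm(s.vertices, axis=1)
        np.testing.assert_allclose(r, 8.5, rtol=1e-14)
        assert s.faces.shape[0] == 20 * 4**refinement

    def test_refined_volume_close_to_closed_form(self):
        s = make_sphere_surface(8.5, refinement=4)
        assert s.enclosed_volume == pytest.approx(SPHERE_VOLUME, rel=0.005)

    def test_invalid_radius(self):
        with pytest.raises(GeometryError):
            make_sphere_surface(-1.0)


class TestSurfaceFromLabels:
    def test_sphere_volume_within_3_percent(self):
        surf = surface_from_labels(sphere_labels(8.5, 0.1, 1.0))
        assert surf.enclosed_volume == pytest.approx(SPHERE_VOLUME, rel=0.03)

    def test_ellipsoid_volume_within_3_percent(self):
        a, b, c = 10.0, 8.0, 7.0
        sxy, sz = 0.1, 1.0
        n_xy, n_z = 260, 26
        x = (np.arange(n_xy) - (n_xy - 1) / 2) * sxy
        z = (np.arange(n_z) - (n_z - 1) / 2) * sz
        zz, yy, xx = np.meshgrid(z, x, x, indexing="ij")
        mask = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0
        surf = surface_from_labels(LabelStack(mask, sxy, sz))
        assert surf.enclosed_volume == pytest.approx(4 / 3 * np.pi * a * b * c, rel=0.03)

    def test_smoothing_changes_volume_less_than_1_percent(self):
        lab = sphere_labels(8.5, 0.2, 1.0)
        v0 = surface_from_labels(lab, smoothing_iterations=0).enclosed_volume
        v10 = surface_from_labels(lab, smoothing_iterations=10).enclosed_volume
        assert abs(v10 - v0) / v0 < 0.01

    def test_unsmoothed_surface_matches_label_volume_within_voxel_layer(self):
        from compax.imaging import label_volume

        lab = sphere_labels(8.5, 0.2, 1.0)
        v_surf = surface_from_labels(lab, smoothing_iterations=0).enclosed_volume
        v_lab = label_volume(lab)
        # one voxel layer over the sphere area at the isosurface grid spacing
        layer = 4 * np.pi * 8.5**2 * 1.0
        assert abs(v_surf - v_lab) < layer

    def test_border_touching_bead_rejected(self):
        lab = sphere_labels(8.5, 0.2, 1.0, margin=-0.5)
        with pytest.raises(GeometryError):
            surface_from_labels(lab)

    def test_too_few_slices_rejected(self):
        mask = np.zeros((5, 20, 20), bool)
        mask[2, 8:12, 8:12] = True
        with pytest.raises(GeometryError):
            surface_from_labels(LabelStack(mask, 0.5, 1.0))


class TestTetrahedralize:
    def test_sphere_volume_matches_closed_form(self):
        surf = make_sphere_surface(8.5, refinement=3)
        mesh = tetrahedralize(surf)
        assert mesh_volume(mesh) == pytest.approx(SPHERE_VOLUME, rel=0.01)
        # and equals the enclosed surface volume much more tightly
        assert mesh_volume(mesh) == pytest.approx(surf.enclosed_volume, rel=1e-9)

    def test_all_signed_volumes_positive(self):
        mesh = tetrahedralize(make_sphere_surface(5.0, refinement=2))
        assert (mesh.corner_volumes() > 0).all()

    def test_refining_max_tet_volume_increases_element_count(self):
        surf = make_sphere_surface(5.0, refinement=2)
        coarse = tetrahedralize(surf, max_tet_volume=8.0)
        fine = tetrahedralize(surf, max_tet_volume=4.0)
        assert fine.n_elements > coarse.n_elements

    def test_surface_vertices_preserved_exactly(self):
        surf = make_sphere_surface(5.0, refinement=2)
        mesh = tetrahedralize(surf)
        np.testing.assert_array_equal(mesh.nodes[: surf.vertices.shape[0]], surf.vertices)

    def test_open_surface_rejected(self):
        from compax.geometry import TriSurfaceMesh

        surf = make_sphere_surface(5.0, refinement=1)
        broken = TriSurfaceMesh(surf.vertices, surf.faces[:-1])
        with pytest.raises(GeometryError):
            tetrahedralize(broken)


class TestMeshVolume:
    def test_unit_regular_tetrahedron(self):
        # edge length 1: V = 1/(6 sqrt(2))
        a = 1.0
        nodes = np.array(
            [
                [0, 0, 0],
                [a, 0, 0],
                [a / 2, a * np.sqrt(3) / 2, 0],
                [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3.0)],
            ]
        )
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
        assert mesh_volume(mesh) == pytest.approx(1.0 / (6.0 * np.sqrt(2.0)), rel=1e-12)

    def test_uniform_scaling_cubes_volume(self):
        mesh = tetrahedralize(make_sphere_surface(5.0, refinement=1))
        v = mesh_volume(mesh)
        scaled = mesh.with_nodes(1.7 * mesh.nodes)
        assert mesh_volume(scaled) == pytest.approx(1.7**3 * v, rel=1e-12)

    def test_divergence_theorem_identity(self):
        mesh = tetrahedralize(make_sphere_surface(5.0, refinement=2))
        assert boundary_volume(mesh) == pytest.approx(mesh_volume(mesh), rel=1e-9)
        quad = promote_to_quadratic(mesh, sphere_projector(np.zeros(3), 5.0))
        assert boundary_volume(quad) == pytest.approx(mesh_volume(quad), rel=1e-9)

    def test_inverted_element_reported(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, -1.0]])
        with pytest.raises(GeometryError, match="inverted"):
            mesh_volume(TetMesh(nodes, np.array([[0, 1, 2, 3]])))


class TestQuadraticPromotion:
    def test_curved_sphere_mesh_volume_near_exact(self):
        mesh = tetrahedralize(make_sphere_surface(8.5, refinement=2))
        quad = promote_to_quadratic(mesh, sphere_projector(np.zeros(3), 8.5))
        assert mesh_volume(quad) == pytest.approx(SPHERE_VOLUME, rel=1e-3)

    def test_boundary_nodes_on_sphere(self):
        mesh = tetrahedralize(make_sphere_surface(8.5, refinement=1))
        quad = promote_to_quadratic(mesh, sphere_projector(np.zeros(3), 8.5))
        r = np.linalg.norm(quad.nodes[quad.surface_node_ids], axis=1)
        np.testing.assert_allclose(r, 8.5, rtol=1e-12)

    def test_roundtrip_render_mesh_volume(self, noiseless_stack):
        from compax.imaging import segment_bead

        surf = surface_from_labels(segment_bead(noiseless_stack))
        assert surf.enclosed_volume == pytest.approx(SPHERE_VOLUME, rel=0.03)
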