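"""Geometry and topology primitives of the shell mesh."""

import numpy as np
import pytest

from epishell.mesh import (ShellMesh, basal_volume, cell_graph_distances,
                           cell_volume, cell_volumes, detect_self_overlap,
                           face_area, junction_lengths, lumen_volume,
                           midplane_surface, polygon_area,
                           surface_face_areas, topological_distance,
                           validate_mesh)
from epishell.seeding import fixture_shell
from conftest import hexagonal_pillbox


class TestValidation:
    def test_dodecahedron_counts(self, dodecahedron):
        d = validate_mesh(dodecahedron)
        assert d.ok
        assert (d.n_vertices, d.n_junctions, d.n_cells) == (20, 30, 12)
        assert d.euler_characteristic == 2

    def test_large_shell_euler_counts(self):
        # E = 3 (N_c - 2), V = 2 (N_c - 2) for any 3-valent sphere tiling
        m = fixture_shell("small_thomson_dual", n_cells=300, v_lumen=100.0)
        d = validate_mesh(m)
        assert d.ok
        assert d.n_junctions == 894
        assert d.n_vertices == 596

    def test_four_valent_vertex_is_reported(self, dodecahedron):
        m = dodecahedron.copy()
        loop = m.cells[0]
        outsider = next(v for v in range(m.n_vertices) if v not in loop)
        loop[0] = outsider                    # outsider now borders 4 cells
        m.invalidate_topology()
        d = validate_mesh(m)
        assert not d.ok
        assert any(f"vertex {outsider}" in e and "valence 4" in e
                   for e in d.errors)

    def test_all_shells_are_orientable(self, shell64):
        assert validate_mesh(shell64[0]).ok


class TestAreas:
    def test_planar_unit_square(self):
        sq = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        assert polygon_area(sq) == pytest.approx(1.0, abs=1e-14)

    def test_planar_regular_hexagon(self):
        ang = np.pi / 3 * np.arange(6)
        hexagon = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        # side 1 -> area 3 sqrt(3) / 2
        assert polygon_area(hexagon) == pytest.approx(3 * np.sqrt(3) / 2,
                                                      rel=1e-14)

    def test_nonplanar_quad_matches_fan_triangles(self):
        quad = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.1], [0, 1, 0]],
                        dtype=float)
        cent = quad.mean(axis=0)
        expect = sum(
            0.5 * np.linalg.norm(np.cross(quad[i] - cent,
                                          quad[(i + 1) % 4] - cent))
            for i in range(4))
        assert polygon_area(quad) == pytest.approx(expect, rel=1e-14)

    def test_degenerate_face_has_zero_area(self):
        assert polygon_area(np.zeros((5, 3))) == 0.0

    def test_face_area_lookup_matches_vectorized(self, relaxed32):
        mesh, _ = relaxed32
        aa = surface_face_areas(mesh, "apical")
        assert face_area(mesh, ("apical", 3)) == pytest.approx(aa[3])


class TestVolumes:
    def test_unit_cuboid_cell(self):
        box = hexagonal_pillbox(side=1.0, height=1.0, nsides=4)
        assert cell_volume(box, 0) == pytest.approx(1.0, rel=1e-12)

    def test_hexagonal_prism_closed_form(self):
        # volume 1 when height = 1 / area, area = (3 sqrt(3)/2) s^2
        s = 0.8
        area = 1.5 * np.sqrt(3) * s ** 2
        box = hexagonal_pillbox(side=s, height=1.0 / area, nsides=6)
        assert cell_volume(box, 0) == pytest.approx(1.0, rel=1e-12)

    def test_orientation_flip_negates_volume(self, dodecahedron):
        flipped = ShellMesh(dodecahedron.apical, dodecahedron.basal,
                            [list(reversed(c)) for c in dodecahedron.cells])
        assert np.allclose(cell_volumes(flipped),
                           -cell_volumes(dodecahedron), rtol=1e-12)

    def test_lumen_volume_of_triangulated_sphere(self, concentric):
        expect = 4.0 / 3.0 * np.pi * 2.879 ** 3
        assert lumen_volume(concentric) == pytest.approx(expect, rel=0.02)

    def test_space_conservation(self, relaxed32):
        # cells + lumen exactly fill the basal envelope
        mesh, _ = relaxed32
        total = cell_volumes(mesh).sum() + lumen_volume(mesh)
        assert total == pytest.approx(basal_volume(mesh), rel=1e-9)

    def test_degenerate_flat_apical_surface(self, dodecahedron):
        m = dodecahedron.copy()
        m.apical[:, 2] = 0.0
        m.apical[:, :2] = 0.0
        assert lumen_volume(m) == pytest.approx(0.0, abs=1e-12)


class TestRigidMotionInvariance:
    def test_areas_and_volumes_invariant(self, relaxed32):
        mesh, _ = relaxed32
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.standard_normal(3)
        moved = ShellMesh(mesh.apical @ q.T + shift,
                          mesh.basal @ q.T + shift,
                          [list(c) for c in mesh.cells])
        assert np.allclose(surface_face_areas(moved, "apical"),
                           surface_face_areas(mesh, "apical"), rtol=1e-12)
        assert np.allclose(cell_volumes(moved), cell_volumes(mesh),
                           rtol=1e-12)


class TestMidplane:
    def test_concentric_spheres_midplane_radius(self, concentric):
        mid = midplane_surface(concentric)
        r = 0.5 * (2.879 + 4.573)
        assert mid.volume == pytest.approx(4 / 3 * np.pi * r ** 3, rel=0.02)
        assert mid.area == pytest.approx(4 * np.pi * r ** 2, rel=0.02)

    def test_coincident_surfaces_give_midplane_identical(self, dodecahedron):
        m = ShellMesh(dodecahedron.apical, dodecahedron.apical,
                      dodecahedron.cells)
        mid = midplane_surface(m)
        assert np.allclose(mid.vertices[:m.n_vertices], m.apical)
        assert mid.volume == pytest.approx(lumen_volume(m), rel=1e-12)

    def test_any_valid_shell_positive(self, relaxed32):
        mid = midplane_surface(relaxed32[0])
        assert mid.area > 0 and mid.volume > 0


class TestTopologicalDistance:
    def test_self_distance_zero(self, dodecahedron):
        assert topological_distance(dodecahedron, 4, 4) == 0

    def test_neighbours_distance_one(self, dodecahedron):
        a, b = dodecahedron.topology.edge_cells[0]
        assert topological_distance(dodecahedron, int(a), int(b)) == 1

    def test_dodecahedron_antipodal_distance(self, dodecahedron):
        d = cell_graph_distances(dodecahedron)
        assert d.max() == 3
        assert (d[0] == 3).sum() == 1          # unique antipodal cell


class TestSelfOverlap:
    def test_convex_shell_is_clean(self, relaxed32):
        assert not detect_self_overlap(relaxed32[0])

    def test_vertex_pushed_through_wall_detected(self, relaxed32):
        m = relaxed32[0].copy()
        m.basal[0] = -m.basal[0]              # through the opposite wall
        assert detect_self_overlap(m)


def test_junction_mid_length_definition(relaxed32):
    mesh, _ = relaxed32
    la, lb, mid = junction_lengths(mesh)
    assert np.allclose(mid, 0.5 * (la + lb))
    assert (mid >= 0).all()
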