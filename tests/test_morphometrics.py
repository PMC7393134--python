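"""Shape statistics: reduced volume, h/c, delta, pair correlations,
anisometry."""

import numpy as np
import pytest

from epishell import morphometrics as mm
from epishell.mesh import ShellMesh
from epishell.seeding import fixture_shell

from conftest import hexagonal_pillbox


def spheroid_reduced_volume(a, c):
    """Closed-form reduced volume of a spheroid with semi-axes (a, a, c)."""
    vol = 4 / 3 * np.pi * a * a * c
    if c < a:                                  # oblate
        e = np.sqrt(1 - (c / a) ** 2)
        area = 2 * np.pi * a ** 2 * (1 + (1 - e ** 2) / e * np.arctanh(e))
    elif c > a:                                # prolate
        e = np.sqrt(1 - (a / c) ** 2)
        area = 2 * np.pi * a ** 2 * (1 + c / (a * e) * np.arcsin(e))
    else:
        area = 4 * np.pi * a ** 2
    return 6 * np.sqrt(np.pi) * vol / area ** 1.5


class TestReducedVolume:
    def test_sphere_is_one(self, concentric):
        assert mm.reduced_volume(concentric) == pytest.approx(1.0, abs=0.02)

    def test_oblate_spheroid_closed_form(self, concentric):
        m = ShellMesh(concentric.apical * [1, 1, 0.5],
                      concentric.basal * [1, 1, 0.5], concentric.cells)
        expect = spheroid_reduced_volume(1.0, 0.5)
        # cross-check the oracle against the equal-volume-sphere route:
        # v = (A_sphere / A)^(3/2)
        r = 0.5 ** (1 / 3)
        vol, area = 4 / 3 * np.pi * 0.5, 8.6720
        assert expect == pytest.approx((4 * np.pi * r ** 2 / area) ** 1.5,
                                       abs=1e-3)
        assert mm.reduced_volume(m) == pytest.approx(expect, abs=0.02)

    def test_isoperimetric_bound_and_monotonicity(self, concentric):
        vs = []
        for cz in [1.0, 0.8, 0.6, 0.4, 0.25]:
            m = ShellMesh(concentric.apical * [1, 1, cz],
                          concentric.basal * [1, 1, cz], concentric.cells)
            vs.append(mm.reduced_volume(m))
        assert all(v <= 1.0 for v in vs)
        assert all(b < a for a, b in zip(vs, vs[1:]))


class TestHeightCurvature:
    def test_flat_prism_zero_curvature(self):
        box = hexagonal_pillbox(side=1.0, height=0.7)
        h, c = mm.cell_height_and_curvature(box, 0)
        assert h == pytest.approx(0.7, rel=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_concentric_sphere_cells(self, concentric):
        h, c = mm.cell_heights_and_curvatures(concentric)
        r_mid = 0.5 * (2.879 + 4.573)
        assert np.nanmean(c) == pytest.approx(1 / r_mid, rel=0.05)
        assert np.nanmean(h) == pytest.approx(4.573 - 2.879, rel=0.05)

    def test_swapping_surfaces_flips_curvature_sign(self, concentric):
        swapped = ShellMesh(concentric.basal, concentric.apical,
                            concentric.cells)
        _, c1 = mm.cell_heights_and_curvatures(concentric)
        _, c2 = mm.cell_heights_and_curvatures(swapped)
        assert np.allclose(c2, -c1, rtol=1e-9)


class TestThicknessModulation:
    def test_uniform_height_gives_zero(self):
        d, p = mm.thickness_modulation(np.ones(10), np.linspace(0, 1, 10))
        assert d == 0.0 and p == 1

    def test_correlated_and_anticorrelated_sign(self):
        c = np.linspace(-1, 1, 50)
        h = 1.0 + 0.2 * c
        d, p = mm.thickness_modulation(h, c)
        assert p == +1
        assert d == pytest.approx(0.2 / 1.0, rel=1e-9)
        d2, p2 = mm.thickness_modulation(2.0 - 0.5 * c, c)
        assert p2 == -1 and d2 < 0


class TestHCFit:
    def test_exact_line_recovery(self):
        c = np.linspace(-0.5, 0.8, 40)
        h = 1.2 + 0.3 * c
        n, k = mm.hc_fit(h, c)
        assert (n, k) == (pytest.approx(1.2), pytest.approx(0.3))

    def test_degenerate_spread_flagged(self):
        with pytest.raises(ValueError):
            mm.hc_fit(np.ones(5), np.ones(5))

    def test_collapse_puts_law_on_identity_line(self):
        # data generated from the empirical law collapses onto h' = c'
        rng = np.random.default_rng(0)
        for a, b in [(0.7, 0.5), (0.5, 1.1), (1.1, 0.5)]:
            c = rng.uniform(-1, 1, 30)
            slope = mm.LAMBDA1 + (a - b) * mm.LAMBDA2
            h = mm.flat_intercept(a, b) + slope * c
            hp, cp = mm.collapse_transform(h, c, a, b)
            assert np.allclose(hp, cp, atol=1e-12)


class TestPairCorrelation:
    def test_dodecahedron_pentagon_correlations(self, dodecahedron):
        g = mm.pair_correlation_single(dodecahedron, 5)
        assert g[1:4] == pytest.approx([5.0, 5.0, 1.0])

    def test_counts_sum_to_class_size_minus_one(self, shell64):
        mesh = shell64[0]
        for gamma in (5, 6):
            g = mm.pair_correlation_single(mesh, gamma)
            n_gamma = mm.polygon_class_counts(mesh)[gamma]
            assert g.sum() == pytest.approx(n_gamma - 1, rel=1e-12)

    def test_ensemble_statistics_and_omission(self, dodecahedron, shell64):
        pc = mm.pair_correlation([dodecahedron, dodecahedron], 5)
        assert pc.n_shells == 2 and np.allclose(pc.sd, 0.0)
        # shells without heptagons are omitted and counted
        with pytest.raises(ValueError):
            mm.pair_correlation([dodecahedron], 7)

    def test_polygon_excess_rule(self, shell64):
        counts = mm.polygon_class_counts(shell64[0])
        assert sum((6 - g) * n for g, n in counts.items()) == 12


class TestAnisometry:
    def test_square_face_is_isometric(self):
        box = hexagonal_pillbox(side=1.0, height=1.0, nsides=4)
        kappa, _ = mm.anisometry(box, ("apical", 0))
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_two_to_one_rectangle(self):
        pts = np.array([[1, 0.5, 0], [-1, 0.5, 0], [-1, -0.5, 0],
                        [1, -0.5, 0]], dtype=float)
        m = ShellMesh(pts, pts + [0, 0, 1], [[0, 1, 2, 3], [3, 2, 1, 0]])
        kappa, axis = mm.anisometry(m, ("apical", 0))
        assert kappa == pytest.approx(0.6, rel=1e-12)
        assert abs(axis[0]) == pytest.approx(1.0)        # long axis is x

    def test_near_planar_faces_have_small_third_eigenvalue(self, relaxed32):
        mesh, _ = relaxed32
        for cell in range(0, mesh.n_cells, 7):
            pts = mesh.apical[mesh.cells[cell]]
            rel = pts - pts.mean(axis=0)
            w = np.linalg.eigvalsh(rel.T @ rel / len(rel))
            assert w[0] < 0.2 * w[1]


class TestClassifier:
    def test_sphere_fixture_is_spherical(self, concentric):
        assert mm.classify_morphology(concentric) == "spherical"

    def test_report_fields(self, relaxed32):
        rep = mm.analyze(relaxed32[0], alpha=1.2, beta=1.2)
        assert rep.label == "spherical"
        assert 0 < rep.v <= 1.0
        assert not rep.self_overlap
        assert rep.polygon_counts[5] >= 12
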