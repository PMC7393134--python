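"""Energy terms and the analytic force (gradient) against oracles."""

import numpy as np
import pytest

from epishell import energetics as en
from epishell.mesh import cell_volumes, junction_lengths, lumen_volume
from epishell.seeding import fixture_shell

from conftest import hexagonal_pillbox


def params_for(mesh, v_lumen, **kw):
    return en.ModelParams(alpha=kw.pop("alpha", 1.0),
                          beta=kw.pop("beta", 1.0),
                          v_lumen_target=v_lumen, **kw)


class TestSurfaceEnergy:
    def test_single_unit_cuboid(self):
        # w = alpha a_a + beta a_b + a_l / 2 = 1 + 1 + 4/2 = 4 per cell
        box = hexagonal_pillbox(side=1.0, height=1.0, nsides=4)
        from epishell.mesh import lateral_quad_areas, surface_face_areas
        w_cell = (surface_face_areas(box, "apical")[0]
                  + surface_face_areas(box, "basal")[0]
                  + 0.5 * lateral_quad_areas(box).sum())
        assert w_cell == pytest.approx(4.0, rel=1e-12)

    def test_linearity_in_tensions(self, relaxed32):
        mesh, _ = relaxed32
        p1 = params_for(mesh, 10.0, alpha=0.7, beta=0.4)
        p2 = params_for(mesh, 10.0, alpha=1.4, beta=0.8)
        from epishell.mesh import lateral_quad_areas
        lat = lateral_quad_areas(mesh).sum()
        # doubling alpha and beta doubles the apical+basal part exactly
        assert (en.surface_energy(mesh, p2) - lat) == pytest.approx(
            2 * (en.surface_energy(mesh, p1) - lat), rel=1e-12)


class TestConstraintEnergy:
    def test_all_at_target_is_zero(self, relaxed32):
        mesh, _ = relaxed32
        p = params_for(mesh, lumen_volume(mesh),
                       cell_volume_targets=cell_volumes(mesh))
        assert en.constraint_energy(mesh, p) == pytest.approx(0.0, abs=1e-20)

    def test_lumen_offset_harmonic_value(self, relaxed32):
        # lumen off target by 0.1 at modulus 100 -> (100/2) 0.1^2 = 0.5
        mesh, _ = relaxed32
        p = params_for(mesh, lumen_volume(mesh) + 0.1,
                       cell_volume_targets=cell_volumes(mesh))
        assert en.constraint_energy(mesh, p) == pytest.approx(0.5, rel=1e-9)

    def test_weak_lumen_modulus_lets_volume_drift(self, shell32):
        # with K_lumen ~ 0.001 the relaxed lumen departs strongly from its
        # target and the shell stays round
        from epishell.dynamics import Simulation
        from epishell.morphometrics import reduced_volume
        mesh = shell32.copy()
        p = params_for(mesh, 10.0, alpha=0.7, beta=0.5, k_lumen=0.001)
        Simulation(mesh, p, seed=0).advance(3.0)
        assert abs(lumen_volume(mesh) - 10.0) > 2.0
        assert reduced_volume(mesh) > 0.9


class TestLineTensionEnergy:
    def test_zero_gammas(self, relaxed32):
        mesh, _ = relaxed32
        assert en.line_tension_energy(mesh, params_for(mesh, 10.0)) == 0.0

    def test_single_junction_value(self):
        box = hexagonal_pillbox(side=1.0, height=1.0, nsides=4)
        gam = np.zeros(box.n_junctions)
        gam[2] = 0.2
        p = params_for(box, 1.0, line_tensions=gam)
        la, lb, _ = junction_lengths(box)
        assert en.line_tension_energy(box, p) == pytest.approx(
            0.2 * (la[2] + lb[2]), rel=1e-14)
        assert la[2] == pytest.approx(1.0) and lb[2] == pytest.approx(1.0)

    def test_energy_odd_in_gamma(self, relaxed32):
        mesh, _ = relaxed32
        rng = np.random.default_rng(0)
        gam = rng.normal(0, 0.2, mesh.n_junctions)
        pp = params_for(mesh, 10.0, line_tensions=gam)
        pm = params_for(mesh, 10.0, line_tensions=-gam)
        assert en.line_tension_energy(mesh, pp) == pytest.approx(
            -en.line_tension_energy(mesh, pm), rel=1e-12)


class TestKernelAgreesWithPlainPath:
    def test_energy_terms_match(self, shell32):
        rng = np.random.default_rng(3)
        p = params_for(shell32, 10.0, alpha=0.8, beta=0.5,
                       line_tensions=rng.normal(0, 0.1, shell32.n_junctions))
        rep = en.evaluate(shell32, p)
        assert rep.w_surface == pytest.approx(en.surface_energy(shell32, p),
                                              rel=1e-12)
        assert rep.w_constraint == pytest.approx(
            en.constraint_energy(shell32, p), rel=1e-12)
        assert rep.w_line == pytest.approx(en.line_tension_energy(shell32, p),
                                           rel=1e-12)
        assert np.allclose(rep.cell_volumes, cell_volumes(shell32), rtol=1e-12)
        assert rep.lumen_volume == pytest.approx(lumen_volume(shell32),
                                                 rel=1e-12)


class TestForce:
    def test_matches_finite_differences(self, shell32):
        rng = np.random.default_rng(1)
        p = params_for(shell32, 10.0, alpha=0.8, beta=0.5,
                       line_tensions=rng.normal(0, 0.1, shell32.n_junctions))
        fa, fb = en.total_force(shell32, p)
        h = 1e-6
        for pos, force in ((shell32.apical, fa), (shell32.basal, fb)):
            for v in rng.choice(shell32.n_vertices, 6, replace=False):
                for d in range(3):
                    old = pos[v, d]
                    pos[v, d] = old + h
                    ep = en.total_energy(shell32, p)
                    pos[v, d] = old - h
                    em = en.total_energy(shell32, p)
                    pos[v, d] = old
                    fd = -(ep - em) / (2 * h)
                    assert fd == pytest.approx(force[v, d],
                                               rel=1e-6, abs=1e-6)

    def test_net_force_vanishes(self, relaxed32):
        # translation invariance of the energy
        mesh, params = relaxed32
        fa, fb = en.total_force(mesh, params)
        assert np.abs(fa.sum(axis=0) + fb.sum(axis=0)).max() < 1e-10

    def test_force_transforms_covariantly(self, shell32):
        from epishell.mesh import ShellMesh
        p = params_for(shell32, 10.0, alpha=0.8, beta=0.5)
        fa, _ = en.total_force(shell32, p)
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rot = ShellMesh(shell32.apical @ q.T, shell32.basal @ q.T,
                        shell32.cells)
        fa_rot, _ = en.total_force(rot, p)
        assert np.allclose(fa_rot, fa @ q.T, atol=1e-9)

    def test_relaxed_state_has_small_force(self, relaxed32):
        mesh, params = relaxed32
        fa, fb = en.total_force(mesh, params)
        scale = np.abs(fa).max() + np.abs(fb).max()
        assert scale < 0.05      # near-stationary after t = 3


class TestRelaxedConstraints:
    def test_volumes_near_targets_at_modulus_100(self, relaxed32):
        # the harmonic constraint leaves an equilibrium offset of order
        # (dw/dV)/K, a few percent at modulus 100
        mesh, params = relaxed32
        assert lumen_volume(mesh) == pytest.approx(params.v_lumen_target,
                                                   rel=0.01)
        assert np.allclose(cell_volumes(mesh), 1.0, rtol=0.05)
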