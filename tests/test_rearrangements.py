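"""T1 mechanics, flip legality, and the OU tension process."""

import numpy as np
import pytest

from epishell.mesh import validate_mesh
from epishell.rearrangements import (DELTA_L, SEPARATION, apply_t1,
                                     fluctuation_t1_trigger, ou_update,
                                     t1_info, t1_legal)


def polygon_imbalance(mesh):
    sizes = np.array([len(c) for c in mesh.cells])
    return ((6 - sizes) * 1).sum()


def first_legal_junction(mesh, predicate=None):
    for j in range(mesh.n_junctions):
        if t1_legal(mesh, j) and (predicate is None or predicate(j)):
            return j
    raise AssertionError("no legal junction found")


class TestApplyT1:
    def test_side_counts_change_by_one(self, relaxed32):
        mesh = relaxed32[0].copy()
        j = first_legal_junction(mesh)
        info = t1_info(mesh, j)
        before = {c: len(mesh.cells[c]) for c in range(mesh.n_cells)}
        apply_t1(mesh, j)
        delta = {c: len(mesh.cells[c]) - before[c]
                 for c in range(mesh.n_cells)
                 if len(mesh.cells[c]) != before[c]}
        assert delta == {info.cell_l: -1, info.cell_r: -1,
                         info.cell_a: +1, info.cell_b: +1}

    def test_topology_counts_preserved(self, relaxed32):
        mesh = relaxed32[0].copy()
        nv, ne, nc = mesh.n_vertices, mesh.n_junctions, mesh.n_cells
        apply_t1(mesh, first_legal_junction(mesh))
        d = validate_mesh(mesh)
        assert d.ok
        assert (d.n_vertices, d.n_junctions, d.n_cells) == (nv, ne, nc)
        assert polygon_imbalance(mesh) == 12

    def test_flip_is_involution_on_topology(self, relaxed32):
        mesh = relaxed32[0].copy()
        adjacency_before = set(map(tuple, np.sort(
            mesh.topology.edge_cells, axis=1).tolist()))
        j = first_legal_junction(mesh)
        info = apply_t1(mesh, j)
        # the same vertex pair carries the new junction; flip it back
        u, v = sorted((info.u, info.v))
        j_back = mesh.topology.edge_index[(u, v)]
        apply_t1(mesh, j_back)
        adjacency_after = set(map(tuple, np.sort(
            mesh.topology.edge_cells, axis=1).tolist()))
        assert adjacency_before == adjacency_after

    def test_new_pair_separation_distance(self, relaxed32):
        mesh = relaxed32[0].copy()
        j = first_legal_junction(mesh)
        info = apply_t1(mesh, j)
        d = np.linalg.norm(mesh.apical[info.u] - mesh.apical[info.v])
        assert d == pytest.approx(SEPARATION, rel=1e-9)

    def test_illegal_flip_raises(self, relaxed32):
        mesh = relaxed32[0].copy()
        mesh_with_triangle, tri_cell = _make_triangle_cell(mesh)
        j = next(j for j in range(mesh_with_triangle.n_junctions)
                 if tri_cell in mesh_with_triangle.topology.edge_cells[j])
        with pytest.raises(ValueError):
            apply_t1(mesh_with_triangle, j)


def _make_triangle_cell(mesh):
    """Shrink some cell to a triangle by repeated legal T1s on its edges."""
    while True:
        sizes = [len(c) for c in mesh.cells]
        smallest = int(np.argmin(sizes))
        if sizes[smallest] == 3:
            return mesh, smallest
        topo = mesh.topology
        for j in range(mesh.n_junctions):
            if smallest in topo.edge_cells[j] and t1_legal(mesh, j):
                apply_t1(mesh, j)
                break
        else:
            raise AssertionError("could not shrink any cell to a triangle")


class TestLegality:
    def test_triangle_cell_blocks_flip(self, relaxed32):
        mesh, tri = _make_triangle_cell(relaxed32[0].copy())
        for j in range(mesh.n_junctions):
            if tri in mesh.topology.edge_cells[j]:
                assert not t1_legal(mesh, j)

    def test_generic_junction_is_legal(self, shell64):
        mesh = shell64[0]
        sizes = mesh.topology.cell_sizes
        j = next(j for j in range(mesh.n_junctions)
                 if all(sizes[c] == 6 for c in mesh.topology.edge_cells[j]))
        assert t1_legal(mesh, j)

    def test_duplicate_adjacency_blocks_flip(self, relaxed32):
        # scan flips; whenever the gaining pair is already adjacent the
        # flip must be illegal, and at least one such case must exist
        mesh = relaxed32[0].copy()
        rng = np.random.default_rng(0)
        found = 0
        for _ in range(200):
            legal = [j for j in range(mesh.n_junctions) if t1_legal(mesh, j)]
            j = int(rng.choice(legal))
            apply_t1(mesh, j)
            for jj in range(mesh.n_junctions):
                info = t1_info(mesh, jj)
                pair = (min(info.cell_a, info.cell_b),
                        max(info.cell_a, info.cell_b))
                if (info.cell_a == info.cell_b
                        or pair in mesh.topology.adjacent_pairs):
                    found += 1
                    assert not t1_legal(mesh, jj)
            if found:
                break
        assert found > 0

    def test_dwell_blocked_cells(self, relaxed32):
        mesh = relaxed32[0].copy()
        j = first_legal_junction(mesh)
        info = t1_info(mesh, j)
        assert not t1_legal(mesh, j, blocked_cells={info.cell_a})


class TestOUProcess:
    def test_deterministic_decay_at_zero_noise(self):
        dt, tau = 1e-3, 1.0
        gamma = np.full(8, 0.5)
        rng = np.random.default_rng(0)
        for _ in range(2000):
            gamma = ou_update(gamma, tau, 0.0, dt, rng)
        assert np.allclose(gamma, 0.5 * np.exp(-2.0), rtol=2e-3)

    def test_mean_reverts_to_zero(self):
        dt, tau, sigma = 1e-3, 1.0, 0.15
        rng = np.random.default_rng(1)
        gamma = np.full(4000, 1.0)
        for _ in range(10_000):            # t = 10 tau
            gamma = ou_update(gamma, tau, sigma, dt, rng)
        assert abs(gamma.mean()) < 4 * sigma / np.sqrt(len(gamma))

    def test_stationary_variance_short(self):
        dt, tau, sigma = 1e-3, 1.0, 0.3
        rng = np.random.default_rng(2)
        gamma = np.zeros(4000)
        for _ in range(8000):
            gamma = ou_update(gamma, tau, sigma, dt, rng)
        assert gamma.var() == pytest.approx(sigma ** 2, rel=0.1)


class TestFluctuationTrigger:
    def test_trigger_threshold(self, relaxed32):
        mesh = relaxed32[0]
        ne = mesh.n_junctions
        mids = np.full(ne, 0.5)
        legal = next(j for j in range(ne) if t1_legal(mesh, j))
        mids[legal] = 0.009
        assert fluctuation_t1_trigger(mesh, mid_lengths=mids) == [legal]
        mids[legal] = 0.011
        assert fluctuation_t1_trigger(mesh, mid_lengths=mids) == []

    def test_refractory_junction_not_triggered(self, relaxed32):
        mesh = relaxed32[0]
        ne = mesh.n_junctions
        mids = np.full(ne, 0.5)
        legal = next(j for j in range(ne) if t1_legal(mesh, j))
        mids[legal] = 0.005
        refractory = np.zeros(ne, dtype=bool)
        refractory[legal] = True
        assert fluctuation_t1_trigger(mesh, refractory=refractory,
                                      mid_lengths=mids) == []


class TestThresholdScheme:
    def test_subthreshold_always_selected(self, relaxed32):
        from epishell.rearrangements import active_t1_attempts
        mesh = relaxed32[0]
        ne = mesh.n_junctions
        mids = np.full(ne, 0.5)
        legal = next(j for j in range(ne) if t1_legal(mesh, j))
        mids[legal] = 0.10          # below delta_l = 0.15
        rng = np.random.default_rng(0)
        chosen = active_t1_attempts(mesh, k_t1=0.0, dt=1e-4, rng=rng,
                                    mid_lengths=mids)
        assert chosen == [legal]

    def test_long_junction_selection_probability(self, relaxed32):
        # per-junction probability k dt / E
        mesh = relaxed32[0]
        ne = mesh.n_junctions
        k, dt = 200.0, 1e-4
        p = k * dt / ne
        assert p == pytest.approx(200 * 1e-4 / ne)
        from epishell.rearrangements import active_t1_attempts
        rng = np.random.default_rng(7)
        mids = np.full(ne, 0.5)
        trials, hits = 4000, 0
        for _ in range(trials):
            hits += len(active_t1_attempts(mesh, k_t1=k, dt=dt, rng=rng,
                                           mid_lengths=mids))
        expect = trials * k * dt
        assert hits == pytest.approx(expect, abs=4 * np.sqrt(expect))
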