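"""Stochastic cell growth, division, and the coupled lumen-volume rule.

Quiescent cells enter a growth period at constant rate 1/tau_d (tau_d =
2000, the expected time until a cell next divides); a growing cell's
target volume then increases linearly at rate 1/tau_g (tau_g = 1) and the
cell divides as soon as it doubles, with the mitotic plane connecting a
random pair of opposing lateral sides.  The preferred lumen volume of a
growing shell follows the same matching rule used to compare shells of
different size: the lumen volume v(x) at tissue volume x satisfies

    (v + x)^(1/3) - v^(1/3) = 400^(1/3) - 100^(1/3),

anchored at v(300) = 100, which keeps the tissue-tension threshold for a
spherical shape independent of shell size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from . import energetics as en
from .dynamics import DT, Schedule, Simulation, Trajectory
from .mesh import ShellMesh

TAU_D = 2000.0
TAU_G = 1.0

# constant on the right-hand side of the lumen matching rule
_LUMEN_CONST = 400.0 ** (1 / 3) - 100.0 ** (1 / 3)


@dataclasses.dataclass
class GrowthState:
    """Per-cell growth phase and target volumes (standalone API; the
    simulation driver keeps the equivalent state internally)."""

    growing: np.ndarray
    targets: np.ndarray
    tau_d: float = TAU_D
    tau_g: float = TAU_G

    @classmethod
    def quiescent(cls, n_cells: int, tau_d: float = TAU_D, tau_g: float = TAU_G):
        return cls(np.zeros(n_cells, dtype=bool), np.ones(n_cells),
                   tau_d, tau_g)


# --------------------------------------------------------------------------
# lumen volume rule


def lumen_target(tissue_volume: float) -> float:
    """Preferred lumen volume for a shell of the given total tissue volume.

    Monotone increasing; equals 100 at 300.  Below the minimal tissue
    volume (~20.3) the matching rule has no nonnegative solution.
    """
    x = float(tissue_volume)
    if x <= 0:
        raise ValueError("tissue volume must be positive")
    if x ** (1 / 3) < _LUMEN_CONST:
        raise ValueError(
            f"no nonnegative lumen volume matches tissue volume {x:.3g} "
            f"(needs at least {_LUMEN_CONST ** 3:.3g})")

    def f(v):
        return (v + x) ** (1 / 3) - v ** (1 / 3) - _LUMEN_CONST

    hi = max(x, 1.0)
    while f(hi) > 0:
        hi *= 4.0
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def lumen_target_array(tissue_volumes: np.ndarray,
                       v_init: float = 100.0) -> np.ndarray:
    """Vectorized Newton solve of the lumen rule (warm-started)."""
    x = np.asarray(tissue_volumes, dtype=float)
    v = np.full(x.shape, max(v_init, 1e-6))
    for _ in range(40):
        f = (v + x) ** (1 / 3) - v ** (1 / 3) - _LUMEN_CONST
        fp = ((v + x) ** (-2 / 3) - v ** (-2 / 3)) / 3.0
        step = f / fp
        v = np.maximum(v - step, 1e-12)
        if np.max(np.abs(f)) < 1e-12:
            break
    return v


# --------------------------------------------------------------------------
# division


def divide_cell(mesh: ShellMesh, cell: int, rng) -> int:
    """Split a cell across a random pair of opposing lateral sides.

    A new vertex is inserted at the midpoint of each chosen side's apical
    and basal edge and the daughters are joined by a new junction between
    them; the basal trace of the mitotic plane mirrors the apical one
    (shared topology).  Counts change by N_c + 1, E + 3, V + 2 per surface,
    preserving the Euler relation.  Returns the id of the appended
    daughter; the other daughter keeps the parent's id.
    """
    loop = mesh.cells[cell]
    n = len(loop)
    if n < 4:
        raise ValueError("cannot divide a triangular cell")
    i = int(rng.integers(n))
    j = (i + n // 2) % n
    a, b = loop[i], loop[(i + 1) % n]
    c, d = loop[j], loop[(j + 1) % n]

    nv = mesh.n_vertices
    p, q = nv, nv + 1
    mesh.apical = np.vstack([mesh.apical,
                             0.5 * (mesh.apical[a] + mesh.apical[b]),
                             0.5 * (mesh.apical[c] + mesh.apical[d])])
    mesh.basal = np.vstack([mesh.basal,
                            0.5 * (mesh.basal[a] + mesh.basal[b]),
                            0.5 * (mesh.basal[c] + mesh.basal[d])])

    def insert_on_directed_edge(other_cell_loop, frm, to, new_vertex):
        m = len(other_cell_loop)
        for k in range(m):
            if other_cell_loop[k] == frm and other_cell_loop[(k + 1) % m] == to:
                other_cell_loop.insert(k + 1, new_vertex)
                return
        raise ValueError("directed edge not found in neighbour loop")

    # neighbours hold the reversed directed edges (b -> a) and (d -> c)
    topo = mesh.topology
    n1 = _other_cell(topo, cell, a, b)
    n2 = _other_cell(topo, cell, c, d)
    insert_on_directed_edge(mesh.cells[n1], b, a, p)
    insert_on_directed_edge(mesh.cells[n2], d, c, q)

    # daughter loops: p..b..c..q and q..d..a..p
    if j > i:
        mid = loop[i + 1:j + 1]
        rest = loop[j + 1:] + loop[:i + 1]
    else:
        mid = loop[i + 1:] + loop[:j + 1]
        rest = loop[j + 1:i + 1]
    daughter1 = [p] + mid + [q]
    daughter2 = [q] + rest + [p]
    mesh.cells[cell] = daughter1
    mesh.cells.append(daughter2)
    mesh.invalidate_topology()
    return len(mesh.cells) - 1


def _other_cell(topo, cell, u, v):
    j = topo.edge_index[(min(u, v), max(u, v))]
    cl, cr = topo.edge_cells[j]
    return int(cr) if cl == cell else int(cl)


# --------------------------------------------------------------------------
# per-step semantics (unit-test surface; the driver uses event sampling)


def growth_step(mesh: ShellMesh, state: GrowthState, dt: float, rng):
    """One explicit step of the growth process.

    Each quiescent cell enters growth with probability dt/tau_d; growing
    targets increase by dt/tau_g; any cell reaching target 2 divides
    immediately (triangular cells wait for a rearrangement first).
    """
    quiescent = np.nonzero(~state.growing)[0]
    enter = quiescent[rng.random(len(quiescent)) < dt / state.tau_d]
    state.growing[enter] = True
    state.targets[state.growing] += dt / state.tau_g
    for c in np.nonzero(state.targets >= 2.0)[0]:
        if len(mesh.cells[c]) < 4:
            continue                      # postponed until a T1 frees it
        new_id = divide_cell(mesh, int(c), rng)
        state.targets[c] = 1.0
        state.targets = np.append(state.targets, 1.0)
        state.growing[c] = False
        state.growing = np.append(state.growing, False)
    return state


# --------------------------------------------------------------------------
# protocol


def run_growth_protocol(alpha: float, beta: float, seed: int = 0, *,
                        n_start: int = 100, n_end: int = 300,
                        schedule: Schedule | None = None,
                        tau_d: float = TAU_D, tau_g: float = TAU_G,
                        dt: float = DT, t_limit: float | None = None,
                        snapshot_every: float | None = 50.0,
                        log_every: float = 10.0,
                        e_ref: int = 894) -> Trajectory:
    """Grow a shell from ``n_start`` to ``n_end`` cells.

    The preferred lumen volume tracks the total tissue target volume via
    the matching rule; an optional active-T1 schedule (in reference-shell
    units; per-junction rates are matched through the junction count
    ``e_ref`` of the 300-cell reference) runs on top.  Expected duration is
    about tau_d * ln(n_end / n_start).
    """
    from .seeding import SeedSpec, build_initial_shell
    v0 = lumen_target(n_start)
    params = en.ModelParams(alpha=alpha, beta=beta, v_lumen_target=v0)
    mesh = build_initial_shell(SeedSpec(n_start, v0, seed=seed), params=params)
    mesh.time = 0.0
    sim = Simulation(mesh, params, scheme="threshold", schedule=schedule,
                     dt=dt, seed=seed, growth=True, tau_g=tau_g, tau_d=tau_d,
                     couple_lumen=True, n_cells_stop=n_end,
                     kt1_edge_ref=e_ref if schedule is not None else None)
    traj = Trajectory([], [], sim.energy_log, sim.events, mesh, sim)
    if t_limit is None:
        t_limit = 5.0 * tau_d
    sim.advance(t_limit, log_every=log_every, snapshot_every=snapshot_every,
                trajectory=traj)
    traj.final_mesh = sim.mesh
    return traj
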