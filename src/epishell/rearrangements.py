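"""T1 neighbour exchanges and fluctuating junctional tensions.

Two activity schemes generate T1 transitions:

* threshold scheme — a junction whose projected mid-length drops below the
  threshold ``DELTA_L`` flips with probability one; longer junctions flip
  stochastically at rate ``k_T1 / E`` per junction (``E`` junctions total),
  so the whole shell attempts active flips at rate ``k_T1``.
* fluctuating-tension scheme — every junction carries an Ornstein-Uhlenbeck
  line tension acting on its apical and basal edge; a flip is initiated
  only when the mid-length falls below ``TRIGGER_LENGTH``.

The mechanical move is identical in both schemes: the edge is collapsed to
its midpoint, held as a four-cell rosette for ``DWELL_TIME``, then the four
surrounding cells swap neighbours and the new vertex pair is separated by
``SEPARATION`` perpendicular to the old edge.  A junction created by a
flip is refractory to further threshold-triggered flips until it has grown
past the trigger length once.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mesh import ShellMesh, junction_lengths

# model constants (dimensionless, lengths in units of the cell-volume scale)
DELTA_L = 0.15          # threshold-scheme trigger mid-length
TRIGGER_LENGTH = 0.01   # fluctuating-tension-scheme trigger mid-length
DWELL_TIME = 2e-3       # rosette dwell before resolution
SEPARATION = 5e-4       # distance between the separated new vertices
OU_TAU = 1.0            # tension turnover time scale


@dataclasses.dataclass
class JunctionState:
    """Per-junction state arrays, aligned with ``mesh.topology.edges``.

    ``gamma`` are the fluctuating line tensions; ``refractory`` marks
    junctions exempt from threshold-triggered flips (fresh T1 products and
    junctions whose flip was found illegal) until they regrow past the
    trigger length.  Values survive topology rebuilds keyed by the sorted
    pair of adjacent cells, which uniquely identifies a junction.
    """

    gamma: np.ndarray
    refractory: np.ndarray

    @classmethod
    def zeros(cls, n_junctions: int):
        return cls(np.zeros(n_junctions), np.zeros(n_junctions, dtype=bool))

    def remap(self, old_edge_cells: np.ndarray, new_edge_cells: np.ndarray,
              fresh_pairs=()):
        """Carry state across a topology rebuild.

        Junctions keep their state by adjacent-cell pair; pairs in
        ``fresh_pairs`` (newly created junctions) start with gamma 0 and
        refractory True; unseen pairs start clean.
        """
        table = {}
        for j, (a, b) in enumerate(old_edge_cells):
            table[(min(a, b), max(a, b))] = (self.gamma[j], self.refractory[j])
        fresh = {(min(a, b), max(a, b)) for a, b in fresh_pairs}
        ne = len(new_edge_cells)
        gamma = np.zeros(ne)
        refractory = np.zeros(ne, dtype=bool)
        for j, (a, b) in enumerate(new_edge_cells):
            key = (min(a, b), max(a, b))
            if key in fresh:
                refractory[j] = True
            elif key in table:
                gamma[j], refractory[j] = table[key]
        self.gamma, self.refractory = gamma, refractory
        return self


@dataclasses.dataclass
class T1Info:
    """Combinatorics of one junction flip: edge (u, v), losing cells
    (L holds the directed edge u->v, R the reverse), gaining cells A (the
    third cell at u) and B (the third cell at v)."""

    junction: int
    u: int
    v: int
    cell_l: int
    cell_r: int
    cell_a: int
    cell_b: int


def t1_info(mesh: ShellMesh, junction: int) -> T1Info:
    topo = mesh.topology
    u, v = (int(x) for x in topo.edges[junction])
    cl, cr = (int(x) for x in topo.edge_cells[junction])
    vc = topo.vertex_cells
    a = [int(c) for c in vc[u] if c not in (cl, cr) and c >= 0]
    b = [int(c) for c in vc[v] if c not in (cl, cr) and c >= 0]
    if len(a) != 1 or len(b) != 1:
        raise ValueError(f"junction {junction} is not in a 3-valent "
                         "neighbourhood")
    return T1Info(junction, u, v, cl, cr, a[0], b[0])


def t1_legal(mesh: ShellMesh, junction: int, blocked_cells=frozenset()) -> bool:
    """A flip is legal unless it would create a 2-gon (a losing cell is a
    triangle), duplicate an existing adjacency (the gaining cells already
    neighbours, or identical), or touch a cell in rosette dwell."""
    try:
        info = t1_info(mesh, junction)
    except ValueError:
        return False
    cells = mesh.cells
    if len(cells[info.cell_l]) <= 3 or len(cells[info.cell_r]) <= 3:
        return False
    if info.cell_a == info.cell_b:
        return False
    pair = (min(info.cell_a, info.cell_b), max(info.cell_a, info.cell_b))
    if pair in mesh.topology.adjacent_pairs:
        return False
    involved = {info.cell_l, info.cell_r, info.cell_a, info.cell_b}
    if involved & set(blocked_cells):
        return False
    return True


def collapse_junction(mesh: ShellMesh, junction: int):
    """Move both vertex pairs of the junction to their midpoints (rosette).

    Returns (pre-flip mid-length, apical edge direction, basal edge
    direction) for the later resolution.
    """
    topo = mesh.topology
    u, v = (int(x) for x in topo.edges[junction])
    da = mesh.apical[v] - mesh.apical[u]
    db = mesh.basal[v] - mesh.basal[u]
    mid_len = 0.5 * (np.linalg.norm(da) + np.linalg.norm(db))
    mesh.apical[u] = mesh.apical[v] = 0.5 * (mesh.apical[u] + mesh.apical[v])
    mesh.basal[u] = mesh.basal[v] = 0.5 * (mesh.basal[u] + mesh.basal[v])
    return mid_len, da, db


def _remove_from_loop(loop, vertex):
    loop.remove(vertex)


def _insert_before(loop, anchor, vertex):
    loop.insert(loop.index(anchor), vertex)


def _loop_neighbours(loop, vertex):
    i = loop.index(vertex)
    return loop[i - 1], loop[(i + 1) % len(loop)]


def _separation_direction(mesh, info, old_dir, surface):
    """Unit vector along which the new vertex pair opens: perpendicular to
    the collapsed edge, pointing from cell R's centroid toward cell L's
    (u stays in L, v stays in R)."""
    pos = mesh.apical if surface == "apical" else mesh.basal
    c_l = pos[mesh.cells[info.cell_l]].mean(axis=0)
    c_r = pos[mesh.cells[info.cell_r]].mean(axis=0)
    w = c_l - c_r
    n = np.linalg.norm(old_dir)
    if n > 1e-12:
        e = old_dir / n
        w = w - (w @ e) * e
    nw = np.linalg.norm(w)
    if nw < 1e-12:                      # degenerate: any perpendicular
        e = old_dir / max(n, 1e-300)
        w = np.cross(e, np.array([0.317, 0.587, 0.745]))
        nw = np.linalg.norm(w)
    return w / nw


def resolve_t1(mesh: ShellMesh, info: T1Info, old_dir_apical, old_dir_basal,
               separation: float = SEPARATION):
    """Reassign connectivity around a collapsed junction and separate the
    new vertex pair.

    The four surrounding cells swap neighbours: the losing cells L, R drop
    a vertex each, the gaining cells A, B insert one each, and the edge
    (u, v) ends up between A and B.  The same reconnection applies to the
    apical network, the basal network and the lateral faces (shared
    topology).  Cell side-counts change by (-1, -1, +1, +1).
    """
    u, v = info.u, info.v
    cells = mesh.cells
    loop_l = cells[info.cell_l]
    loop_r = cells[info.cell_r]
    # L holds ... x_L, u, v, z_L ...  R holds ... t_R, v, u, y_R ...
    x_l, nxt = _loop_neighbours(loop_l, u)
    if nxt != v:
        raise ValueError("junction vertices not consecutive in losing cell")
    z_l = _loop_neighbours(loop_l, v)[1]
    t_r, nxt = _loop_neighbours(loop_r, v)
    if nxt != u:
        raise ValueError("junction vertices not consecutive in losing cell")
    y_r = _loop_neighbours(loop_r, u)[1]

    dir_a = _separation_direction(mesh, info, old_dir_apical, "apical")
    dir_b = _separation_direction(mesh, info, old_dir_basal, "basal")

    _remove_from_loop(loop_l, v)
    _remove_from_loop(loop_r, u)
    # A gains v between y_R and u; B gains u between z_L and v
    loop_a = cells[info.cell_a]
    loop_b = cells[info.cell_b]
    pa, sa = _loop_neighbours(loop_a, u)
    if pa != y_r:
        raise ValueError("inconsistent winding around gaining cell")
    _insert_before(loop_a, u, v)
    pb, sb = _loop_neighbours(loop_b, v)
    if pb != z_l:
        raise ValueError("inconsistent winding around gaining cell")
    _insert_before(loop_b, v, u)

    half = 0.5 * separation
    mesh.apical[u] += half * dir_a
    mesh.apical[v] -= half * dir_a
    mesh.basal[u] += half * dir_b
    mesh.basal[v] -= half * dir_b
    mesh.invalidate_topology()
    return info


def apply_t1(mesh: ShellMesh, junction: int, separation: float = SEPARATION,
             collapse: bool = True) -> T1Info:
    """Perform a complete T1 on a junction in one call (no dwell).

    The time-resolved pathway (midpoint collapse, rosette dwell, delayed
    resolution) lives in the simulation driver; this operation collapses
    and resolves immediately, which is the appropriate primitive for
    topology work and tests.
    """
    if not t1_legal(mesh, junction):
        raise ValueError(f"T1 on junction {junction} is not legal")
    info = t1_info(mesh, junction)
    if collapse:
        _, da, db = collapse_junction(mesh, junction)
    else:
        da = mesh.apical[info.v] - mesh.apical[info.u]
        db = mesh.basal[info.v] - mesh.basal[info.u]
    return resolve_t1(mesh, info, da, db, separation)


# --------------------------------------------------------------------------
# activity schemes


def ou_update(gamma: np.ndarray, tau: float, sigma: float, dt: float, rng):
    """One Euler-Maruyama step of the junctional-tension OU process.

    gamma <- gamma (1 - dt/tau) + N(0,1) sqrt(2 sigma^2 dt / tau); the
    stationary distribution has mean 0 and variance sigma^2 (up to
    O(dt/tau) discretization).  Noise is independent across junctions.
    """
    amp = np.sqrt(2.0 * sigma ** 2 * dt / tau)
    return gamma * (1.0 - dt / tau) + amp * rng.standard_normal(gamma.shape)


def active_t1_attempts(mesh: ShellMesh, k_t1: float, dt: float, rng,
                       refractory=None, blocked_cells=frozenset(),
                       mid_lengths=None, delta_l: float = DELTA_L):
    """Junctions selected for a flip this step under the threshold scheme.

    Sub-threshold junctions (mid-length < delta_l, not refractory) are
    selected with probability one; every other junction independently with
    probability ``k_t1 dt / E``.  Selections are filtered by
    :func:`t1_legal` and thinned to at most one per cell.
    """
    if mid_lengths is None:
        _, _, mid_lengths = junction_lengths(mesh)
    ne = mesh.n_junctions
    if refractory is None:
        refractory = np.zeros(ne, dtype=bool)
    short = (mid_lengths < delta_l) & ~refractory
    candidates = set(np.nonzero(short)[0].tolist())
    if k_t1 > 0:
        p = k_t1 * dt / ne
        hits = np.nonzero(rng.random(ne) < p)[0]
        candidates |= set(hits.tolist())
    chosen = []
    used_cells = set(blocked_cells)
    for j in sorted(candidates):
        if not t1_legal(mesh, j, used_cells):
            continue
        info = t1_info(mesh, j)
        chosen.append(j)
        used_cells |= {info.cell_l, info.cell_r, info.cell_a, info.cell_b}
    return chosen


def fluctuation_t1_trigger(mesh: ShellMesh, refractory=None,
                           blocked_cells=frozenset(), mid_lengths=None,
                           trigger_length: float = TRIGGER_LENGTH):
    """Junctions to flip under the fluctuating-tension scheme: mid-length
    below the trigger length, legal, not refractory; at most one per cell."""
    if mid_lengths is None:
        _, _, mid_lengths = junction_lengths(mesh)
    ne = mesh.n_junctions
    if refractory is None:
        refractory = np.zeros(ne, dtype=bool)
    short = (mid_lengths < trigger_length) & ~refractory
    chosen = []
    used_cells = set(blocked_cells)
    for j in np.nonzero(short)[0]:
        if not t1_legal(mesh, int(j), used_cells):
            continue
        info = t1_info(mesh, int(j))
        chosen.append(int(j))
        used_cells |= {info.cell_l, info.cell_r, info.cell_a, info.cell_b}
    return chosen
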