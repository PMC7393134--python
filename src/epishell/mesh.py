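"""Polygonal-prism mesh of a closed epithelial shell.

A shell is a single layer of prism-like cells: every cell has a polygonal
apical side facing the lumen, a basal side of identical topology facing
outward, and one lateral quadrilateral per cell-cell junction.  Apical and
basal vertex ``i`` correspond to one another, so a single set of cyclic
vertex loops (one per cell) describes both surface networks.

Conventions
-----------
* Positions are dimensionless, in units of the cube root of the cell volume.
* Cell loops are stored counter-clockwise as seen from outside the shell,
  so the centroid-fan triangles of a face in stored order have normals
  pointing away from the lumen.
* Every vertex is 3-valent and every junction borders exactly two cells;
  on the closed surface ``V - E + N_c = 2``.
* Faces are generally non-planar; areas and volumes are always evaluated on
  the centroid-fan triangulation, which is smooth in the vertex positions.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree


# --------------------------------------------------------------------------
# core data structure


class ShellMesh:
    """Paired apical/basal polygonal networks with shared topology.

    Parameters
    ----------
    apical, basal : (Nv, 3) float arrays
        Vertex positions of the two surfaces; index ``i`` on the apical
        surface pairs with index ``i`` on the basal surface.
    cells : sequence of integer sequences
        Cyclic vertex loop of every cell, counter-clockwise viewed from
        outside the shell.
    time : float
        Simulation time attached to this state (units of the intrinsic
        relaxation time).
    """

    def __init__(self, apical, basal, cells, time=0.0):
        self.apical = np.ascontiguousarray(apical, dtype=np.float64)
        self.basal = np.ascontiguousarray(basal, dtype=np.float64)
        if self.apical.shape != self.basal.shape or self.apical.ndim != 2:
            raise ValueError("apical and basal must be (Nv, 3) arrays of equal shape")
        self.cells = [list(map(int, loop)) for loop in cells]
        self.time = float(time)
        self._topo = None

    # -- basic counts ------------------------------------------------------

    @property
    def n_vertices(self):
        return self.apical.shape[0]

    @property
    def n_cells(self):
        return len(self.cells)

    @property
    def n_junctions(self):
        return self.topology.edges.shape[0]

    # -- derived topology --------------------------------------------------

    @property
    def topology(self) -> "MeshTopology":
        if self._topo is None:
            self._topo = MeshTopology.from_cells(self.cells, self.n_vertices)
        return self._topo

    def invalidate_topology(self):
        """Drop cached derived structures after a connectivity edit."""
        self._topo = None

    def copy(self) -> "ShellMesh":
        m = ShellMesh(self.apical.copy(), self.basal.copy(),
                      [list(c) for c in self.cells], self.time)
        return m


@dataclasses.dataclass
class MeshTopology:
    """Flat index arrays derived from the cell loops.

    ``edges[e] = (u, v)`` with the directed edge ``u -> v`` appearing in the
    loop of ``edge_cells[e, 0]`` (and ``v -> u`` in ``edge_cells[e, 1]``).
    The centroid-fan triangle arrays index triangles as (face centroid,
    ``tri_i``, ``tri_j``) per consecutive loop pair.
    """

    cells_flat: np.ndarray       # concatenated loops, int32
    cells_off: np.ndarray        # (Nc+1,) offsets into cells_flat
    cell_sizes: np.ndarray       # (Nc,) polygon class of each cell
    edges: np.ndarray            # (E, 2) vertex ids
    edge_cells: np.ndarray       # (E, 2) (cell keeping u->v, cell keeping v->u)
    tri_cell: np.ndarray         # (T,) owning cell of each fan triangle
    tri_i: np.ndarray            # (T,) first loop vertex of the triangle
    tri_j: np.ndarray            # (T,) second loop vertex
    n_vertices: int
    edge_u: np.ndarray = None    # contiguous copies of the edge columns
    edge_v: np.ndarray = None    # (kept for the jit kernel)
    edge_l: np.ndarray = None
    edge_r: np.ndarray = None

    def __post_init__(self):
        self.edge_u = np.ascontiguousarray(self.edges[:, 0])
        self.edge_v = np.ascontiguousarray(self.edges[:, 1])
        self.edge_l = np.ascontiguousarray(self.edge_cells[:, 0])
        self.edge_r = np.ascontiguousarray(self.edge_cells[:, 1])
        self._vertex_cells = None
        self._adjacent_pairs = None
        self._edge_index = None

    @property
    def vertex_cells(self) -> np.ndarray:
        """(Nv, 3) cells incident to each (3-valent) vertex; -1 padding."""
        if self._vertex_cells is None:
            vc = np.full((self.n_vertices, 3), -1, dtype=np.int32)
            fill = np.zeros(self.n_vertices, dtype=np.int32)
            for c in range(len(self.cell_sizes)):
                for v in self.cells_flat[self.cells_off[c]:self.cells_off[c + 1]]:
                    if fill[v] < 3:
                        vc[v, fill[v]] = c
                    fill[v] += 1
            self._vertex_cells = vc
        return self._vertex_cells

    @property
    def adjacent_pairs(self) -> set:
        """Set of sorted cell pairs sharing a junction."""
        if self._adjacent_pairs is None:
            self._adjacent_pairs = {
                (min(a, b), max(a, b)) for a, b in self.edge_cells}
        return self._adjacent_pairs

    @property
    def edge_index(self) -> dict:
        """Sorted vertex pair -> junction index."""
        if self._edge_index is None:
            self._edge_index = {(int(u), int(v)): j
                                for j, (u, v) in enumerate(self.edges)}
        return self._edge_index

    @classmethod
    def from_cells(cls, cells: Sequence[Sequence[int]], n_vertices: int):
        sizes = np.array([len(c) for c in cells], dtype=np.int32)
        off = np.zeros(len(cells) + 1, dtype=np.int32)
        np.cumsum(sizes, out=off[1:])
        flat = np.fromiter((v for loop in cells for v in loop),
                           dtype=np.int32, count=off[-1])
        tri_i = flat
        tri_j = np.empty_like(flat)
        for c in range(len(cells)):
            a, b = off[c], off[c + 1]
            tri_j[a:b - 1] = flat[a + 1:b]
            tri_j[b - 1] = flat[a]
        tri_cell = np.repeat(np.arange(len(cells), dtype=np.int32), sizes)

        directed = {}
        for c, loop in enumerate(cells):
            n = len(loop)
            for k in range(n):
                u, v = loop[k], loop[(k + 1) % n]
                if (u, v) in directed:
                    raise ValueError(f"directed edge {(u, v)} repeated; "
                                     "inconsistent orientation")
                directed[(u, v)] = c
        edge_list, edge_cell_list = [], []
        for (u, v), c in directed.items():
            if u < v:
                if (v, u) not in directed:
                    raise ValueError(f"edge {(u, v)} borders only one cell")
                edge_list.append((u, v))
                edge_cell_list.append((c, directed[(v, u)]))
        edges = np.array(edge_list, dtype=np.int32).reshape(-1, 2)
        edge_cells = np.array(edge_cell_list, dtype=np.int32).reshape(-1, 2)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        return cls(flat, off, sizes, edges[order], edge_cells[order],
                   tri_cell, tri_i, tri_j, n_vertices)

    def cell_adjacency(self) -> csr_matrix:
        e = self.edge_cells
        n = len(self.cell_sizes)
        data = np.ones(2 * len(e), dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return csr_matrix((data, (rows, cols)), shape=(n, n))


# --------------------------------------------------------------------------
# geometry primitives (plain numpy; the fast simulation kernel has its own
# implementation of the same formulas and is cross-checked against these)


def _fan_geometry(positions, topo):
    """Per-face centroid-fan triangle geometry for one surface.

    Returns (centroids, cross products e1 x e2, per-triangle tet volumes).
    Triangle t is (centroid[tri_cell[t]], positions[tri_i[t]],
    positions[tri_j[t]]); tet volumes are signed, from the origin.
    """
    counts = topo.cell_sizes.astype(np.float64)
    nc = len(counts)
    cent = np.empty((nc, 3))
    for k in range(3):
        cent[:, k] = np.bincount(topo.tri_cell, weights=positions[topo.tri_i, k],
                                 minlength=nc)
    cent /= counts[:, None]
    p0 = cent[topo.tri_cell]
    p1 = positions[topo.tri_i]
    p2 = positions[topo.tri_j]
    cr = np.cross(p1 - p0, p2 - p0)
    vtet = np.einsum("ij,ij->i", p0, np.cross(p1, p2)) / 6.0
    return cent, cr, vtet


def surface_face_areas(mesh: ShellMesh, surface: str) -> np.ndarray:
    """Per-cell area of the apical or basal face (centroid-fan)."""
    topo = mesh.topology
    pos = mesh.apical if surface == "apical" else mesh.basal
    _, cr, _ = _fan_geometry(pos, topo)
    tri_a = 0.5 * np.linalg.norm(cr, axis=1)
    return np.bincount(topo.tri_cell, weights=tri_a, minlength=mesh.n_cells)


def lateral_quad_areas(mesh: ShellMesh) -> np.ndarray:
    """Per-junction area of the lateral quad (a_u, a_v, b_v, b_u).

    The quad is generally non-planar; its area is the centroid-fan value.
    Each junction's quad is shared by the two adjacent cells, so the summed
    lateral area of a cell counts each of its quads once.
    """
    topo = mesh.topology
    u, v = topo.edges[:, 0], topo.edges[:, 1]
    corners = np.stack([mesh.apical[u], mesh.apical[v],
                        mesh.basal[v], mesh.basal[u]], axis=1)  # (E,4,3)
    cent = corners.mean(axis=1)
    areas = np.zeros(len(u))
    for k in range(4):
        p1 = corners[:, k]
        p2 = corners[:, (k + 1) % 4]
        cr = np.cross(p1 - cent, p2 - cent)
        areas += 0.5 * np.linalg.norm(cr, axis=1)
    return areas


def face_area(mesh: ShellMesh, face) -> float:
    """Area of a single face.

    ``face`` is ``("apical", cell)``, ``("basal", cell)`` or
    ``("lateral", junction)``.  Degenerate faces return 0.
    """
    kind, idx = face
    if kind in ("apical", "basal"):
        return float(surface_face_areas(mesh, kind)[idx])
    if kind == "lateral":
        return float(lateral_quad_areas(mesh)[idx])
    raise ValueError(f"unknown face kind {kind!r}")


def polygon_area(points: np.ndarray) -> float:
    """Centroid-fan area of a single (possibly non-planar) polygon."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    nxt = np.roll(pts, -1, axis=0)
    cr = np.cross(pts - c, nxt - c)
    return float(0.5 * np.linalg.norm(cr, axis=1).sum())


def _quad_tet_volumes(mesh):
    """Signed tet-volume of every lateral quad, oriented outward from the
    cell holding the directed edge u -> v (edge_cells[:, 0])."""
    topo = mesh.topology
    u, v = topo.edges[:, 0], topo.edges[:, 1]
    corners = np.stack([mesh.apical[u], mesh.apical[v],
                        mesh.basal[v], mesh.basal[u]], axis=1)
    cent = corners.mean(axis=1)
    vol = np.zeros(len(u))
    for k in range(4):
        p1 = corners[:, k]
        p2 = corners[:, (k + 1) % 4]
        vol += np.einsum("ij,ij->i", cent, np.cross(p1, p2)) / 6.0
    return vol


def cell_volumes(mesh: ShellMesh) -> np.ndarray:
    """Signed volume of every cell via the divergence theorem.

    Positive for correctly oriented cells (loops counter-clockwise seen
    from outside).
    """
    topo = mesh.topology
    _, _, tet_a = _fan_geometry(mesh.apical, topo)
    _, _, tet_b = _fan_geometry(mesh.basal, topo)
    nc = mesh.n_cells
    vol = (np.bincount(topo.tri_cell, weights=tet_b, minlength=nc)
           - np.bincount(topo.tri_cell, weights=tet_a, minlength=nc))
    qv = _quad_tet_volumes(mesh)
    np.add.at(vol, topo.edge_cells[:, 0], qv)
    np.add.at(vol, topo.edge_cells[:, 1], -qv)
    return vol


def cell_volume(mesh: ShellMesh, cell: int) -> float:
    return float(cell_volumes(mesh)[cell])


def lumen_volume(mesh: ShellMesh) -> float:
    """Volume enclosed by the apical surface alone."""
    _, _, tet = _fan_geometry(mesh.apical, mesh.topology)
    return float(tet.sum())


def basal_volume(mesh: ShellMesh) -> float:
    """Volume enclosed by the outer (basal) surface."""
    _, _, tet = _fan_geometry(mesh.basal, mesh.topology)
    return float(tet.sum())


@dataclasses.dataclass
class MidplaneSurface:
    """Closed triangulated surface halfway between apical and basal."""

    vertices: np.ndarray      # midpoint vertices plus face centroids
    triangles: np.ndarray     # (T, 3) indices into ``vertices``
    area: float
    volume: float


def midplane_surface(mesh: ShellMesh) -> MidplaneSurface:
    """Surface through the apical/basal vertex midpoints, fan-triangulated."""
    topo = mesh.topology
    mid = 0.5 * (mesh.apical + mesh.basal)
    cent, cr, tet = _fan_geometry(mid, topo)
    area = float(0.5 * np.linalg.norm(cr, axis=1).sum())
    volume = float(tet.sum())
    verts = np.vstack([mid, cent])
    tris = np.column_stack([mesh.n_vertices + topo.tri_cell,
                            topo.tri_i, topo.tri_j]).astype(np.int32)
    return MidplaneSurface(verts, tris, area, volume)


# --------------------------------------------------------------------------
# validation


@dataclasses.dataclass
class MeshDiagnostics:
    ok: bool
    n_vertices: int
    n_junctions: int
    n_cells: int
    euler_characteristic: int
    valences: np.ndarray
    face_sizes: np.ndarray
    errors: list

    def __bool__(self):
        return self.ok


def validate_mesh(mesh: ShellMesh) -> MeshDiagnostics:
    """Structural audit: valence, Euler relation, face sizes, orientation.

    Orientation consistency (all apical faces coherently oriented toward
    the lumen) is enforced by requiring every junction to appear exactly
    once in each direction among the cell loops.
    """
    errors = []
    valence = np.zeros(mesh.n_vertices, dtype=np.int32)
    sizes = []
    for c, loop in enumerate(mesh.cells):
        sizes.append(len(loop))
        if len(loop) < 3:
            errors.append(f"cell {c} has fewer than 3 vertices")
        if len(set(loop)) != len(loop):
            errors.append(f"cell {c} repeats a vertex in its loop")
        for v in loop:
            valence[v] += 1
    try:
        topo = mesh.topology
        n_edges = topo.edges.shape[0]
    except ValueError as exc:
        errors.append(str(exc))
        n_edges = -1
    bad = np.nonzero(valence != 3)[0]
    for v in bad:
        errors.append(f"vertex {v} has valence {valence[v]} (expected 3)")
    euler = mesh.n_vertices - n_edges + mesh.n_cells if n_edges >= 0 else 0
    if n_edges >= 0 and euler != 2:
        errors.append(f"Euler characteristic {euler} != 2")
    return MeshDiagnostics(ok=not errors,
                           n_vertices=mesh.n_vertices,
                           n_junctions=n_edges,
                           n_cells=mesh.n_cells,
                           euler_characteristic=euler,
                           valences=valence,
                           face_sizes=np.array(sizes, dtype=np.int32),
                           errors=errors)


# --------------------------------------------------------------------------
# junction geometry


def junction_lengths(mesh: ShellMesh):
    """Apical, basal and projected mid-lengths of every junction.

    The mid-length is the length of the junction viewed as an edge halfway
    between the corresponding apical and basal edges: (l_a + l_b) / 2.
    """
    topo = mesh.topology
    u, v = topo.edges[:, 0], topo.edges[:, 1]
    la = np.linalg.norm(mesh.apical[u] - mesh.apical[v], axis=1)
    lb = np.linalg.norm(mesh.basal[u] - mesh.basal[v], axis=1)
    return la, lb, 0.5 * (la + lb)


# --------------------------------------------------------------------------
# topological distances


def cell_graph_distances(mesh: ShellMesh) -> np.ndarray:
    """All-pairs topological distance on the cell adjacency graph."""
    adj = mesh.topology.cell_adjacency()
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    return d.astype(np.int64)


def topological_distance(mesh: ShellMesh, cell_a: int, cell_b: int) -> int:
    """Integer shortest path between two cells; 1 for nearest neighbours."""
    if cell_a == cell_b:
        return 0
    adj = mesh.topology.cell_adjacency()
    indptr, indices = adj.indptr, adj.indices
    dist = {cell_a: 0}
    q = deque([cell_a])
    while q:
        c = q.popleft()
        for nb in indices[indptr[c]:indptr[c + 1]]:
            if nb not in dist:
                dist[nb] = dist[c] + 1
                if nb == cell_b:
                    return dist[nb]
                q.append(nb)
    raise ValueError("cell adjacency graph is not connected")


# --------------------------------------------------------------------------
# self-overlap screening


def _surface_triangles(mesh: ShellMesh):
    """Fan triangles of both surfaces with synthetic vertex ids.

    Ids: apical vertex i -> i; basal i -> Nv+i; apical centroid of cell c ->
    2Nv+c; basal centroid -> 2Nv+Nc+c.  Used to exclude triangle pairs that
    share a vertex from the intersection test.
    """
    topo = mesh.topology
    nv, nc = mesh.n_vertices, mesh.n_cells
    out_pts, out_ids = [], []
    for surf, pos, voff, coff in (("apical", mesh.apical, 0, 2 * nv),
                                  ("basal", mesh.basal, nv, 2 * nv + nc)):
        cent, _, _ = _fan_geometry(pos, topo)
        p0 = cent[topo.tri_cell]
        p1 = pos[topo.tri_i]
        p2 = pos[topo.tri_j]
        out_pts.append(np.stack([p0, p1, p2], axis=1))
        ids = np.column_stack([coff + topo.tri_cell,
                               voff + topo.tri_i, voff + topo.tri_j])
        out_ids.append(ids)
    return np.concatenate(out_pts), np.concatenate(out_ids)


def _interval_on_line(tri, dv, axis, eps):
    """Interval of the plane-intersection line covered by one triangle.

    ``dv`` are the signed distances of the triangle's vertices to the other
    triangle's plane; the line is parametrized by the coordinate ``axis``.
    """
    p = tri[:, axis]
    ts = []
    for a in range(3):
        b = (a + 1) % 3
        if (dv[a] > eps and dv[b] < -eps) or (dv[a] < -eps and dv[b] > eps):
            ts.append(p[a] + (p[b] - p[a]) * dv[a] / (dv[a] - dv[b]))
        elif abs(dv[a]) <= eps:
            ts.append(p[a])
    if len(ts) < 2:
        return np.inf, -np.inf
    return min(ts), max(ts)


def _tri_tri_intersect(t1, t2, eps=1e-12):
    """Batched Moller-style triangle-triangle overlap test.

    t1, t2: (P, 3, 3) coordinate arrays of candidate pairs.  The plane
    rejection is vectorized; the exact interval test runs on the few
    survivors.  Coplanar / grazing contacts count as non-intersecting.
    """
    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    dv1 = np.einsum("pj,pij->pi", n2, t1 - t2[:, :1])   # dist of t1 verts to t2 plane
    dv2 = np.einsum("pj,pij->pi", n1, t2 - t1[:, :1])

    def same_side(dv):
        return (dv > eps).all(axis=1) | (dv < -eps).all(axis=1)

    coplanar = (np.abs(dv1) <= eps).all(axis=1)
    alive = ~(same_side(dv1) | same_side(dv2) | coplanar)
    result = np.zeros(len(t1), dtype=bool)
    for r in np.nonzero(alive)[0]:
        d = np.cross(n1[r], n2[r])
        axis = int(np.argmax(np.abs(d)))
        lo1, hi1 = _interval_on_line(t1[r], dv1[r], axis, eps)
        lo2, hi2 = _interval_on_line(t2[r], dv2[r], axis, eps)
        if min(hi1, hi2) - max(lo1, lo2) > eps:
            result[r] = True
    return result


def detect_self_overlap(mesh: ShellMesh) -> bool:
    """True iff two non-adjacent surface triangles intersect.

    Screens final shapes only; transient overlaps during dynamics are
    expected and are not checked (steric repulsion is not part of the
    model).  Triangles sharing a vertex (or a face centroid) are skipped.
    """
    tris, ids = _surface_triangles(mesh)
    cent = tris.mean(axis=1)
    rad = np.linalg.norm(tris - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cent)
    pairs = tree.query_pairs(2.0 * rad.max(), output_type="ndarray")
    if len(pairs) == 0:
        return False
    keep = (np.linalg.norm(cent[pairs[:, 0]] - cent[pairs[:, 1]], axis=1)
            <= rad[pairs[:, 0]] + rad[pairs[:, 1]])
    pairs = pairs[keep]
    if len(pairs) == 0:
        return False
    ids_a = ids[pairs[:, 0]]
    ids_b = ids[pairs[:, 1]]
    shared = (ids_a[:, :, None] == ids_b[:, None, :]).any(axis=(1, 2))
    pairs = pairs[~shared]
    if len(pairs) == 0:
        return False
    chunk = 200_000
    for s in range(0, len(pairs), chunk):
        block = pairs[s:s + chunk]
        hit = _tri_tri_intersect(tris[block[:, 0]], tris[block[:, 1]])
        if hit.any():
            return True
    return False
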