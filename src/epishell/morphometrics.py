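"""Shape statistics of epithelial shells.

Reduced volume of the midplane surface, per-cell thickness/curvature
pairs, relative thickness modulation, h(c) fits and their rescaling
collapse, topological pair correlations of polygon classes, face
anisometry, and a heuristic morphology classifier.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse.csgraph import connected_components

from . import mesh as meshmod
from .mesh import ShellMesh

SQRT_PI = np.sqrt(np.pi)

# flat-epithelium intercept prefactor 2^(1/3) / 3^(1/6)
H0_PREFACTOR = 2.0 ** (1 / 3) / 3.0 ** (1 / 6)
# empirical slope law k = lambda1 + (alpha - beta) * lambda2
LAMBDA1 = -0.059
LAMBDA2 = 0.45


# --------------------------------------------------------------------------
# reduced volume


def reduced_volume(mesh: ShellMesh) -> float:
    """v = 6 sqrt(pi) V / A^(3/2) of the midplane surface (1 for a sphere)."""
    mid = meshmod.midplane_surface(mesh)
    return reduced_volume_of(mid.area, mid.volume)


def reduced_volume_of(area: float, volume: float) -> float:
    return 6.0 * SQRT_PI * volume / area ** 1.5


# --------------------------------------------------------------------------
# thickness and curvature


def _face_area_centroids(mesh: ShellMesh, surface: str):
    """Area-weighted centroid and area of every apical or basal face."""
    topo = mesh.topology
    pos = mesh.apical if surface == "apical" else mesh.basal
    cent, cr, _ = meshmod._fan_geometry(pos, topo)
    tri_area = 0.5 * np.linalg.norm(cr, axis=1)
    tri_cent = (cent[topo.tri_cell] + pos[topo.tri_i] + pos[topo.tri_j]) / 3.0
    nc = mesh.n_cells
    areas = np.bincount(topo.tri_cell, weights=tri_area, minlength=nc)
    ac = np.empty((nc, 3))
    for k in range(3):
        ac[:, k] = np.bincount(topo.tri_cell,
                               weights=tri_area * tri_cent[:, k], minlength=nc)
    ok = areas > 0
    ac[ok] /= areas[ok, None]
    return ac, areas


def cell_heights_and_curvatures(mesh: ShellMesh):
    """Per-cell (h, c): height and truncated-cone mean curvature.

    h is the distance between the area centroids of the apical and basal
    side; c approximates the mean curvature of a truncated cone with the
    same apical area a_a, basal area a_b and height:
    c = (2/h)(sqrt(a_b) - sqrt(a_a)) / (sqrt(a_b) + sqrt(a_a)), positive
    when the basal (outer) side is the larger one.  Cells with h = 0 get
    NaN curvature.
    """
    ca, aa = _face_area_centroids(mesh, "apical")
    cb, ab = _face_area_centroids(mesh, "basal")
    h = np.linalg.norm(cb - ca, axis=1)
    sa, sb = np.sqrt(aa), np.sqrt(ab)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(h > 0, (2.0 / h) * (sb - sa) / (sb + sa), np.nan)
    return h, c


def cell_height_and_curvature(mesh: ShellMesh, cell: int):
    h, c = cell_heights_and_curvatures(mesh)
    return float(h[cell]), float(c[cell])


def thickness_modulation(h, c, robust: bool = False):
    """Relative thickness modulation delta = p * Dh / mean(h).

    Dh is half the full h range (or half the 2.5-97.5 percentile span with
    ``robust``); p = +1 when thickness correlates with curvature (taller
    cells at high-curvature spots), -1 when anticorrelated.
    """
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    ok = np.isfinite(h) & np.isfinite(c)
    h, c = h[ok], c[ok]
    if len(h) < 3 or np.ptp(h) == 0:
        return 0.0, 1
    if robust:
        lo, hi = np.percentile(h, [2.5, 97.5])
    else:
        lo, hi = h.min(), h.max()
    dh = 0.5 * (hi - lo)
    corr = np.corrcoef(c, h)[0, 1]
    p = 1 if (not np.isfinite(corr) or corr >= 0) else -1
    return float(p * dh / h.mean()), p


def hc_fit(h, c):
    """Least-squares line h = n + k c through the per-cell scatter."""
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    ok = np.isfinite(h) & np.isfinite(c)
    h, c = h[ok], c[ok]
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct curvature values to fit")
    k, n = np.polyfit(c, h, 1)
    return float(n), float(k)


def flat_intercept(alpha: float, beta: float) -> float:
    """Flat-epithelium cell height (2^(1/3)/3^(1/6)) (alpha+beta)^(2/3),
    the expected vertical intercept of the h(c) line."""
    return H0_PREFACTOR * (alpha + beta) ** (2 / 3)


def collapse_transform(h, c, alpha, beta, lambda1=LAMBDA1, lambda2=LAMBDA2):
    """Rescale (h, c) so shells at different tensions share one line.

    h -> h - (2^(1/3)/3^(1/6))(alpha+beta)^(2/3) removes the tissue-tension
    part; c -> [lambda1 + (alpha-beta) lambda2] c maps curvature through
    the empirical slope law, putting the scatter on the identity line.
    """
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    return h - flat_intercept(alpha, beta), (lambda1 + (alpha - beta) * lambda2) * c


# --------------------------------------------------------------------------
# topological pair correlations


def polygon_class_counts(mesh: ShellMesh) -> dict:
    sizes = mesh.topology.cell_sizes
    return {int(g): int((sizes == g).sum()) for g in np.unique(sizes)}


def pair_correlation_single(mesh: ShellMesh, gamma: int) -> np.ndarray:
    """g_gamma(d) for one shell: average number of gamma-gons at
    topological distance d >= 1 from a gamma-gon; sums to n_gamma - 1."""
    sizes = mesh.topology.cell_sizes
    idx = np.nonzero(sizes == gamma)[0]
    if len(idx) == 0:
        raise ValueError(f"shell has no {gamma}-sided cells")
    dist = meshmod.cell_graph_distances(mesh)
    sub = dist[np.ix_(idx, idx)]
    dmax = int(dist.max())
    g = np.zeros(dmax + 1)
    for d in range(1, dmax + 1):
        g[d] = (sub == d).sum() / len(idx)
    return g


@dataclasses.dataclass
class PairCorrelation:
    """Ensemble-averaged g_gamma(d) with per-distance standard deviation."""

    gamma: int
    d: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_shells: int
    n_omitted: int


def pair_correlation(meshes, gamma: int) -> PairCorrelation:
    """Mean and sd of g_gamma(d) over an ensemble of shells.

    Shells with no gamma-sided cells are omitted (and counted).
    """
    rows = []
    omitted = 0
    for m in meshes:
        try:
            rows.append(pair_correlation_single(m, gamma))
        except ValueError:
            omitted += 1
    if not rows:
        raise ValueError(f"no shell in the ensemble has {gamma}-sided cells")
    dmax = max(len(r) for r in rows)
    table = np.zeros((len(rows), dmax))
    for i, r in enumerate(rows):
        table[i, :len(r)] = r
    return PairCorrelation(gamma, np.arange(dmax), table.mean(axis=0),
                           table.std(axis=0), len(rows), omitted)


# --------------------------------------------------------------------------
# anisometry


def anisometry(mesh: ShellMesh, face):
    """(kappa, long axis) of a face from its vertex gyration tensor.

    kappa = (g1 - g2)/(g1 + g2) with g1 >= g2 the two largest eigenvalues;
    0 for isometric faces, toward 1 for elongated ones.  Faces are nearly
    planar, so the third eigenvalue is small but finite.
    """
    surface, cell = face
    pos = mesh.apical if surface == "apical" else mesh.basal
    pts = pos[mesh.cells[cell]]
    rel = pts - pts.mean(axis=0)
    gyr = rel.T @ rel / len(rel)
    w, vecs = np.linalg.eigh(gyr)
    g1, g2 = w[2], w[1]
    kappa = (g1 - g2) / (g1 + g2) if g1 + g2 > 0 else 0.0
    return float(kappa), vecs[:, 2]


# --------------------------------------------------------------------------
# morphology classification


@dataclasses.dataclass
class ClassifierConfig:
    """Thresholds of the heuristic morphology classifier.

    Curvature thresholds are relative to the curvature 1/R of the sphere
    with the shell's midplane volume.  Calibrated once against the four
    reference parameter sets of the fixed-size study (spherical 1.2/1.2,
    stomatocyte 0.7/0.5 passive, budded 1.5/0.3, branched 0.7/0.5 active).
    """

    v_spherical: float = 0.94      # reduced volume above which: spherical
    neg_factor: float = -0.3       # c below this * c_sphere: invaginated
    pos_factor: float = 1.7        # c above this * c_sphere: protrusion
    min_invag_cells: int = 3
    min_lobe_cells: int = 2
    elongation_branched: float = 1.45
    min_lobes_branched: int = 2


@dataclasses.dataclass
class MorphometricsReport:
    v: float
    heights: np.ndarray
    curvatures: np.ndarray
    delta: float
    p: int
    intercept: float | None
    slope: float | None
    polygon_counts: dict
    self_overlap: bool
    label: str


def _lobes(mesh, mask):
    """Connected components of cells selected by ``mask``."""
    adj = mesh.topology.cell_adjacency()
    sel = np.nonzero(mask)[0]
    if len(sel) == 0:
        return []
    sub = adj[np.ix_(sel, sel)]
    n, lab = connected_components(sub, directed=False)
    return [sel[lab == i] for i in range(n)]


def _elongation(points):
    """Aspect ratio sqrt(g1/g2) of a point cloud's gyration tensor."""
    rel = points - points.mean(axis=0)
    w = np.linalg.eigvalsh(rel.T @ rel / len(rel))
    if w[1] <= 1e-12:
        return np.inf
    return float(np.sqrt(w[2] / w[1]))


def classify_morphology(mesh: ShellMesh, report=None,
                        config: ClassifierConfig | None = None,
                        check_overlap: bool = True) -> str:
    """Heuristic morphology label for a final, relaxed snapshot.

    nonphysical: the surface self-overlaps.  spherical: reduced volume
    above threshold.  Otherwise protrusion lobes (connected regions of
    strongly positive per-cell curvature) and invaginations (strongly
    negative curvature) decide between stomatocyte (invagination-
    dominated), branched (several elongated lobes), budded (lobes present
    but round or few), and hybrid.
    """
    cfg = config or ClassifierConfig()
    if check_overlap and meshmod.detect_self_overlap(mesh):
        return "nonphysical"
    v = reduced_volume(mesh)
    if v > cfg.v_spherical:
        return "spherical"
    h, c = cell_heights_and_curvatures(mesh)
    _, p = thickness_modulation(h, c)
    mid = meshmod.midplane_surface(mesh)
    c_sph = (4.0 * np.pi / (3.0 * mid.volume)) ** (1 / 3)
    n_invag = int((c < cfg.neg_factor * c_sph).sum())
    lobes = [l for l in _lobes(mesh, c > cfg.pos_factor * c_sph)
             if len(l) >= cfg.min_lobe_cells]
    # an invaginated cup (anticorrelated thickness: tall cells inside)
    # beats the high-curvature rim that also registers as a "lobe"
    if n_invag >= cfg.min_invag_cells and (p == -1 or not lobes):
        return "stomatocyte"
    if lobes:
        mid_centroids = 0.5 * (_face_area_centroids(mesh, "apical")[0]
                               + _face_area_centroids(mesh, "basal")[0])
        elong = [_elongation(mid_centroids[l]) for l in lobes if len(l) >= 3]
        if (len(lobes) >= cfg.min_lobes_branched and elong
                and np.mean(elong) >= cfg.elongation_branched):
            return "branched"
        return "budded" if n_invag < cfg.min_invag_cells else "hybrid"
    return "hybrid"


def analyze(mesh: ShellMesh, alpha: float | None = None,
            beta: float | None = None,
            config: ClassifierConfig | None = None) -> MorphometricsReport:
    """Full morphometric report for one shell."""
    h, c = cell_heights_and_curvatures(mesh)
    delta, p = thickness_modulation(h, c)
    try:
        n, k = hc_fit(h, c)
    except ValueError:
        n = k = None
    overlap = meshmod.detect_self_overlap(mesh)
    label = ("nonphysical" if overlap else
             classify_morphology(mesh, config=config, check_overlap=False))
    return MorphometricsReport(
        v=reduced_volume(mesh), heights=h, curvatures=c,
        delta=delta, p=p, intercept=n, slope=k,
        polygon_counts=polygon_class_counts(mesh),
        self_overlap=overlap, label=label)
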