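"""Initial spherical shells and small analytic fixtures.

The initial cell packing on the sphere is the dual of the convex hull of a
minimal-energy (Thomson-problem) point configuration: every charge becomes
a cell, every hull triangle an apical vertex, so the resulting tiling is
3-valent by construction.  Basal vertices sit radially outward from their
apical partners at the offset that gives the shell the correct total
volume ``v_lumen + N_c``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull

from .mesh import ShellMesh, lumen_volume, validate_mesh


@dataclasses.dataclass
class SeedSpec:
    """Recipe for an initial shell.

    ``prerelax_time`` is the short passive relaxation (no active T1s) used
    to bring the constructed cell volumes to their targets before activity
    starts; the construction itself leaves them within ~20 % of 1.
    """

    n_cells: int
    v_lumen: float
    seed: int = 0
    prerelax_time: float = 1.0

    def __post_init__(self):
        if self.n_cells < 12:
            raise ValueError("need at least 12 cells for a closed 3-valent shell")
        if self.v_lumen <= 0:
            raise ValueError("lumen volume must be positive")


# --------------------------------------------------------------------------
# Thomson problem


def _thomson_energy_grad(x, n):
    p = x.reshape(n, 3)
    r = np.linalg.norm(p, axis=1, keepdims=True)
    y = p / r
    diff = y[:, None, :] - y[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(d, np.inf)
    energy = 0.5 * (1.0 / d).sum()
    # dE/dy_i = -sum_j (y_i - y_j) / d_ij^3
    gy = -(diff / d[:, :, None] ** 3).sum(axis=1)
    # chain rule through the normalization y = x / |x|
    gx = (gy - (gy * y).sum(axis=1, keepdims=True) * y) / r
    return energy, gx.ravel()


def thomson_points(n: int, rng=None, restarts: int = 3, tol: float = 1e-12):
    """Local minimum of the Coulomb energy of ``n`` unit charges on a sphere.

    Deterministic given the RNG; several random restarts are tried and the
    lowest minimum kept.  Any local minimum whose hull dual is 3-valent is
    an acceptable seed packing (junctional activity randomizes the packing
    during the simulation anyway), but for small ``n`` the global optimum
    (tetrahedron at n=4, icosahedron at n=12) is found reliably.
    """
    if n < 4:
        raise ValueError("need at least 4 points")
    if rng is None:
        rng = np.random.default_rng(0)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    best = None
    for _ in range(restarts):
        x0 = rng.standard_normal((n, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = minimize(_thomson_energy_grad, x0.ravel(), args=(n,),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 10_000, "ftol": tol, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Thomson minimization failed to converge")
    p = best.x.reshape(n, 3)
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def thomson_energy(points: np.ndarray) -> float:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return float(0.5 * (1.0 / d).sum())


# --------------------------------------------------------------------------
# hull dual


def hull_dual(points: np.ndarray):
    """Dual tiling of the convex hull of points on the unit sphere.

    Returns (apical_vertices, cells): one dual vertex per hull triangle
    (the outward-normalized triangle centroid) and one cell per input
    point, its loop ordered counter-clockwise viewed from outside.
    """
    hull = ConvexHull(points)
    simplices = hull.simplices
    cent = points[simplices].mean(axis=1)
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)

    incident = [[] for _ in range(len(points))]
    for t, tri in enumerate(simplices):
        for v in tri:
            incident[v].append(t)
    cells = []
    for i, tris in enumerate(incident):
        r = points[i] / np.linalg.norm(points[i])
        # tangent basis with e1 x e2 = r: increasing angle = CCW from outside
        ref = np.array([1.0, 0.0, 0.0])
        if abs(r[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(ref, r)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(r, e1)
        w = cent[tris] - np.outer(cent[tris] @ r, r)
        ang = np.arctan2(w @ e2, w @ e1)
        cells.append([tris[k] for k in np.argsort(ang)])
    return cent, cells


def basal_offset(v_lumen: float, n_cells: int) -> float:
    """Radial apical-to-basal displacement of the initial spherical shell.

    Difference of the radii of spheres enclosing ``v_lumen + N_c`` and
    ``v_lumen``, so the constructed shell has the right total volume.
    """
    return ((3.0 * (v_lumen + n_cells) / (4.0 * np.pi)) ** (1.0 / 3.0)
            - (3.0 * v_lumen / (4.0 * np.pi)) ** (1.0 / 3.0))


def build_initial_shell(spec: SeedSpec, params=None,
                        prerelax: bool = True) -> ShellMesh:
    """Spherical shell from the Thomson dual, optionally pre-relaxed.

    The apical surface is scaled to enclose ``v_lumen``; basal vertices are
    displaced radially outward by :func:`basal_offset`.  With ``prerelax``
    the shell is relaxed passively (no active T1s) for
    ``spec.prerelax_time`` to correct the initial cell volumes.
    """
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        pts = thomson_points(spec.n_cells, rng)
        try:
            apical, cells = hull_dual(pts)
        except Exception:
            continue
        mesh = _shell_from_dual(apical, cells, spec.v_lumen, spec.n_cells)
        if validate_mesh(mesh).ok:
            break
    else:
        raise RuntimeError("could not build a valid 3-valent dual shell")
    if prerelax and spec.prerelax_time > 0:
        from .dynamics import relax  # deferred: dynamics builds on this module
        mesh = relax(mesh, spec.v_lumen, params=params,
                     t_end=spec.prerelax_time)
    return mesh


def _shell_from_dual(apical_unit, cells, v_lumen, n_cells):
    mesh = ShellMesh(apical_unit, apical_unit, cells)
    v0 = lumen_volume(mesh)
    scale = (v_lumen / v0) ** (1.0 / 3.0)
    apical = apical_unit * scale
    radial = apical / np.linalg.norm(apical, axis=1, keepdims=True)
    basal = apical + basal_offset(v_lumen, n_cells) * radial
    return ShellMesh(apical, basal, cells)


# --------------------------------------------------------------------------
# fixtures


# golden-ratio icosahedron vertices (unit-normalized below)
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICOSAHEDRON = np.array(
    [[0, 1, _PHI], [0, -1, _PHI], [0, 1, -_PHI], [0, -1, -_PHI],
     [1, _PHI, 0], [-1, _PHI, 0], [1, -_PHI, 0], [-1, -_PHI, 0],
     [_PHI, 0, 1], [_PHI, 0, -1], [-_PHI, 0, 1], [-_PHI, 0, -1]],
    dtype=float)
_ICOSAHEDRON /= np.linalg.norm(_ICOSAHEDRON, axis=1, keepdims=True)


def fixture_shell(kind: str, seed: int = 0, **kwargs) -> ShellMesh:
    """Deterministic small meshes for tests and examples.

    kinds:
      ``dodecahedron``             12 pentagonal cells (dual of the icosahedron);
                                   optional ``v_lumen`` (default 8.0)
      ``small_thomson_dual``       ``n_cells`` mixed pentagon/hexagon shell;
                                   optional ``v_lumen``
      ``concentric_spheres``       cells cut from spheres ``r_in``/``r_out``
                                   (per-cell curvature fixture)
    """
    if kind == "dodecahedron":
        v_lumen = kwargs.get("v_lumen", 8.0)
        apical, cells = hull_dual(_ICOSAHEDRON)
        return _shell_from_dual(apical, cells, v_lumen, 12)
    if kind == "small_thomson_dual":
        n_cells = kwargs["n_cells"]
        v_lumen = kwargs.get("v_lumen", 0.3 * n_cells)
        pts = thomson_points(n_cells, np.random.default_rng(seed))
        apical, cells = hull_dual(pts)
        return _shell_from_dual(apical, cells, v_lumen, n_cells)
    if kind == "concentric_spheres":
        r_in = kwargs.get("r_in", 2.879)
        r_out = kwargs.get("r_out", 4.573)
        n_cells = kwargs.get("n_cells", 64)
        pts = thomson_points(n_cells, np.random.default_rng(seed))
        apical_unit, cells = hull_dual(pts)
        return ShellMesh(apical_unit * r_in, apical_unit * r_out, cells)
    raise ValueError(f"unknown fixture kind {kind!r}")
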