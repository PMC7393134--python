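"""Energy terms and per-vertex forces of the shell vertex model.

The dimensionless shell energy (in units of the lateral tension times the
cell volume to the power 2/3) is

    w = sum_cells [ alpha * a_a + beta * a_b + 1/2 * a_l ]
      + K_cell/2 * sum_cells (V_i - V_i^target)^2
      + K_lumen/2 * (V_lumen - v_lumen)^2
      + sum_junctions gamma_i * (l_a,i + l_b,i)

with alpha and beta the apical and basal tensions in units of the lateral
tension, unit preferred cell volume, and very stiff harmonic volume
constraints (modulus 100 by default) standing in for cell and lumen
incompressibility.  Each lateral face is shared by two cells, hence the
factor 1/2; summed over junctions every lateral quad counts exactly once.

Forces are the exact negative gradient of this energy, evaluated by the
jit kernel in :mod:`._kernel`; the plain-numpy energies here provide the
slow independent path used for cross-checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import mesh as meshmod
from ._kernel import energy_and_gradient
from .mesh import ShellMesh


@dataclasses.dataclass
class ModelParams:
    """Dimensionless physical parameters of the shell.

    alpha, beta : apical and basal tensions (units of the lateral tension).
    v_lumen_target : preferred lumen volume (units of the cell volume).
    k_cell, k_lumen : harmonic constraint moduli (default 100; written with
        a K/2 prefactor).
    cell_volume_targets : per-cell preferred volumes; None means 1 for all
        (only the growth protocol moves them).
    line_tensions : per-junction fluctuating tensions gamma_i, aligned with
        ``mesh.topology.edges``; None means 0.
    """

    alpha: float
    beta: float
    v_lumen_target: float
    k_cell: float = 100.0
    k_lumen: float = 100.0
    cell_volume_targets: np.ndarray | None = None
    line_tensions: np.ndarray | None = None

    def __post_init__(self):
        if self.k_cell <= 0 or self.k_lumen <= 0:
            raise ValueError("constraint moduli must be positive")

    def vtargets(self, n_cells: int) -> np.ndarray:
        if self.cell_volume_targets is None:
            return np.ones(n_cells)
        return np.asarray(self.cell_volume_targets, dtype=float)

    def gammas(self, n_junctions: int) -> np.ndarray:
        if self.line_tensions is None:
            return np.zeros(n_junctions)
        return np.asarray(self.line_tensions, dtype=float)


# --------------------------------------------------------------------------
# plain (slow, independent) energy evaluation


def surface_energy(mesh: ShellMesh, params: ModelParams) -> float:
    """alpha * apical area + beta * basal area + half the lateral areas."""
    aa = meshmod.surface_face_areas(mesh, "apical").sum()
    ab = meshmod.surface_face_areas(mesh, "basal").sum()
    al = meshmod.lateral_quad_areas(mesh).sum()
    return float(params.alpha * aa + params.beta * ab + al)


def constraint_energy(mesh: ShellMesh, params: ModelParams) -> float:
    vols = meshmod.cell_volumes(mesh)
    dv = vols - params.vtargets(mesh.n_cells)
    dl = meshmod.lumen_volume(mesh) - params.v_lumen_target
    return float(0.5 * params.k_cell * (dv ** 2).sum()
                 + 0.5 * params.k_lumen * dl ** 2)


def line_tension_energy(mesh: ShellMesh, params: ModelParams) -> float:
    la, lb, _ = meshmod.junction_lengths(mesh)
    return float((params.gammas(mesh.n_junctions) * (la + lb)).sum())


def total_energy(mesh: ShellMesh, params: ModelParams) -> float:
    return (surface_energy(mesh, params)
            + constraint_energy(mesh, params)
            + line_tension_energy(mesh, params))


# --------------------------------------------------------------------------
# fast kernel evaluation


@dataclasses.dataclass
class EnergyReport:
    """Everything the jit kernel returns for one configuration."""

    force_apical: np.ndarray
    force_basal: np.ndarray
    w_surface: float
    w_constraint: float
    w_line: float
    cell_volumes: np.ndarray
    lumen_volume: float
    l_apical: np.ndarray
    l_basal: np.ndarray

    @property
    def energy(self) -> float:
        return self.w_surface + self.w_constraint + self.w_line

    @property
    def mid_lengths(self) -> np.ndarray:
        return 0.5 * (self.l_apical + self.l_basal)


def evaluate(mesh: ShellMesh, params: ModelParams) -> EnergyReport:
    """Energy, forces and junction lengths in one kernel call."""
    topo = mesh.topology
    ga, gb, ws, wc, wl, vols, vlum, la, lb = energy_and_gradient(
        mesh.apical, mesh.basal,
        topo.cells_flat, topo.cells_off,
        topo.edge_u, topo.edge_v, topo.edge_l, topo.edge_r,
        params.gammas(topo.edges.shape[0]),
        params.vtargets(mesh.n_cells),
        float(params.alpha), float(params.beta),
        float(params.k_cell), float(params.k_lumen),
        float(params.v_lumen_target))
    return EnergyReport(-ga, -gb, ws, wc, wl, vols, vlum, la, lb)


def total_force(mesh: ShellMesh, params: ModelParams):
    """Negative energy gradient for every apical and basal vertex."""
    rep = evaluate(mesh, params)
    return rep.force_apical, rep.force_basal
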