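"""Effective elasticity theory of the cell monolayer.

Coarse-graining the prism-cell energy over a surface patch with principal
curvatures c1, c2 and thickness h (cells incompressible, h a = 1) gives a
harmonic energy per unit midplane area

    dw/da = (alpha + beta) + 2 [1 - (alpha - beta)^2 / 4] h^(3/2)
          + (sqrt(h)/8) [c1 + c2 - 2 sqrt(h) (alpha - beta)]^2
          + ((alpha + beta)/4 + h^(3/2)/12 - 1/(4 h^(3/2))) h^2 c1 c2,

i.e. a surface tension (first two terms), a local bending term with
modulus sqrt(h)/8 and spontaneous curvature c0 = 2 sqrt(h)(alpha - beta),
and a Gaussian bending term.  The apico-basal differential tension
alpha - beta therefore acts exactly like a spontaneous curvature, while
the tissue tension alpha + beta sets the flat-equilibrium cell height.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .morphometrics import H0_PREFACTOR

#: default midplane-enclosed volume (units of cell volume) of the
#: reference 300-cell shells, itself a simulation average
V_MIDPLANE_DEFAULT = 223.0
N_CELLS_DEFAULT = 300


@dataclasses.dataclass
class ContinuumParams:
    """Tension pair plus derived continuum quantities at thickness h."""

    alpha: float
    beta: float

    @property
    def tissue_tension(self):
        return self.alpha + self.beta

    @property
    def differential_tension(self):
        return self.alpha - self.beta

    def equilibrium(self):
        return flat_equilibrium(self.tissue_tension)

    def c0(self, h: float | None = None):
        if h is None:
            h = self.equilibrium()[0]
        return spontaneous_curvature(h, self.alpha, self.beta)

    def bending_modulus(self, h: float | None = None):
        if h is None:
            h = self.equilibrium()[0]
        return np.sqrt(h) / 8.0


def energy_density(h, c1, c2, alpha, beta):
    """Elastic energy per unit midplane area; symmetric in (c1, c2)."""
    h = np.asarray(h, dtype=float)
    s, d = alpha + beta, alpha - beta
    h32 = h ** 1.5
    bend = (np.sqrt(h) / 8.0) * (c1 + c2 - 2.0 * np.sqrt(h) * d) ** 2
    gauss = (s / 4.0 + h32 / 12.0 - 1.0 / (4.0 * h32)) * h ** 2 * c1 * c2
    out = s + 2.0 * (1.0 - d ** 2 / 4.0) * h32 + bend + gauss
    return out if out.shape else float(out)


def flat_equilibrium(tissue_tension: float):
    """(h0, a0) of a flat sheet of regular hexagonal prisms.

    Force balance along the cell height of the per-cell energy
    (alpha+beta)/h + (perimeter/2) h at unit cell volume gives
    h0 = (2^(1/3)/3^(1/6)) (alpha+beta)^(2/3) and a0 = 1/h0.
    """
    if tissue_tension <= 0:
        raise ValueError("tissue tension must be positive")
    h0 = H0_PREFACTOR * tissue_tension ** (2 / 3)
    return h0, 1.0 / h0


def hexagon_cell_energy(h, tissue_tension: float):
    """Surface energy of a regular hexagonal prism of unit volume and
    height h; its minimum over h defines the flat equilibrium."""
    h = np.asarray(h, dtype=float)
    area = 1.0 / h
    side = np.sqrt(2.0 * area / (3.0 * np.sqrt(3.0)))
    perimeter = 6.0 * side
    out = tissue_tension * area + 0.5 * perimeter * h
    return out if out.shape else float(out)


def predicted_reduced_volume(alpha: float, beta: float,
                             n_cells: int = N_CELLS_DEFAULT,
                             v_midplane: float = V_MIDPLANE_DEFAULT):
    """Reduced volume of a non-spherical shell, linear in alpha + beta.

    Estimates the midplane area as N_c a0 with the flat-equilibrium cell
    area:  v = 2^(3/2) 3^(3/4) sqrt(pi) v_midplane N_c^(-3/2) (alpha+beta).
    """
    pref = 2.0 ** 1.5 * 3.0 ** 0.75 * np.sqrt(np.pi)
    return pref * v_midplane / n_cells ** 1.5 * (alpha + beta)


def predicted_reduced_volume_slope(n_cells: int = N_CELLS_DEFAULT,
                                   v_midplane: float = V_MIDPLANE_DEFAULT):
    """d v / d(alpha + beta) of the prediction above."""
    return predicted_reduced_volume(0.5, 0.5, n_cells, v_midplane)


def spontaneous_curvature(h, alpha: float, beta: float):
    """c0 = 2 sqrt(h) (alpha - beta); negative on the invaginated
    (stomatocyte) side of the phase diagram."""
    return 2.0 * np.sqrt(h) * (alpha - beta)
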