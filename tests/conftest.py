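"""Shared fixtures: small deterministic shells, reused across the suite."""

import numpy as np
import pytest

from epishell import energetics as en
from epishell.dynamics import Simulation
from epishell.seeding import fixture_shell


@pytest.fixture(scope="session")
def dodecahedron():
    return fixture_shell("dodecahedron")


@pytest.fixture(scope="session")
def shell32():
    """Unrelaxed 32-cell Thomson-dual shell."""
    return fixture_shell("small_thomson_dual", n_cells=32, v_lumen=10.0)


@pytest.fixture(scope="session")
def relaxed32(shell32):
    """32-cell shell passively relaxed to near-equilibrium."""
    mesh = shell32.copy()
    params = en.ModelParams(alpha=1.2, beta=1.2, v_lumen_target=10.0)
    Simulation(mesh, params, seed=0).advance(3.0)
    return mesh, params


@pytest.fixture(scope="session")
def shell64():
    """64-cell shell with the size-matched lumen volume."""
    from epishell.growth import lumen_target
    v = lumen_target(64)
    return fixture_shell("small_thomson_dual", n_cells=64, v_lumen=v), v


@pytest.fixture(scope="session")
def concentric():
    """Cells cut from concentric spheres (curvature fixture)."""
    return fixture_shell("concentric_spheres", r_in=2.879, r_out=4.573,
                         n_cells=256)


def hexagonal_pillbox(side=1.0, height=1.0, nsides=6):
    """Two mirror prism 'cells' closing a polygonal pillbox; cell 0 is a
    regular prism of the given side and height with volume area*height."""
    from epishell.mesh import ShellMesh
    ang = 2 * np.pi * np.arange(nsides) / nsides
    poly = np.column_stack([side * np.cos(ang) / (2 * np.sin(np.pi / nsides)),
                            side * np.sin(ang) / (2 * np.sin(np.pi / nsides)),
                            np.zeros(nsides)])
    apical = poly.copy()
    basal = poly + np.array([0.0, 0.0, height])
    cells = [list(range(nsides)), list(range(nsides))[::-1]]
    return ShellMesh(apical, basal, cells)
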