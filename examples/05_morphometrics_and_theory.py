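"""Morphometrics of packing: pair correlations, anisometry, theory table.

Computes the topological pair correlation of pentagons on the
dodecahedral shell (an exact combinatorial reference), the anisometry of
cell faces, and tabulates the continuum predictions across the tension
range of the phase diagram.
"""

import numpy as np

from epishell.continuum import flat_equilibrium, predicted_reduced_volume, spontaneous_curvature
from epishell.morphometrics import anisometry, pair_correlation_single
from epishell.seeding import fixture_shell

dodeca = fixture_shell("dodecahedron")
g5 = pair_correlation_single(dodeca, 5)
print("dodecahedron pentagon pair correlation g5(d):",
      {d: round(float(g5[d]), 3) for d in range(1, 4)})
# every pentagon sees 5 neighbours, 5 next-nearest cells, 1 antipode

kappa, axis = anisometry(dodeca, ("apical", 0))
print(f"regular pentagon anisometry kappa = {kappa:.3f} (isometric -> 0)")

print("\n alpha+beta    h0      a0     c0(at a-b=0.6)   v_pred(300 cells)")
for s in (1.0, 1.4, 1.9, 2.4):
    h0, a0 = flat_equilibrium(s)
    c0 = spontaneous_curvature(h0, (s + 0.6) / 2, (s - 0.6) / 2)
    v = predicted_reduced_volume((s + 0.6) / 2, (s - 0.6) / 2)
    print(f"   {s:5.2f}    {h0:.4f}  {a0:.4f}      {c0:+.4f}        {min(v, 1.0):.4f}")
# v_pred crosses 1 near alpha+beta = 1.9: the spherical onset of the
# phase diagram; below it the preferred cell shape forces extra area and
# the shell buckles into stomatocyte/budded/branched morphologies.
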