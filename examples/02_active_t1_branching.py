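"""Junctional activity drives a shell away from its passive shape.

Runs the same low-tension shell twice: passively, and with a high initial
active T1 rate that decays linearly to zero.  The active shell ends at a
higher energy (trapped away from the passive minimum) with a lower
reduced volume and topological defects (pentagons/heptagons) rearranged
by the ~thousands of T1 events.
"""

from epishell import ModelParams, Schedule, SeedSpec, build_initial_shell, run_protocol
from epishell.growth import lumen_target
from epishell.interface import E_REFERENCE
from epishell.morphometrics import polygon_class_counts, reduced_volume

alpha, beta, n_cells = 0.7, 0.5, 64
v_lumen = lumen_target(n_cells)
params = ModelParams(alpha=alpha, beta=beta, v_lumen_target=v_lumen)

results = {}
for label, k0 in [("passive", 0.0), ("active", 200.0)]:
    mesh = build_initial_shell(SeedSpec(n_cells, v_lumen, seed=1),
                               params=params)
    mesh.time = 0.0
    schedule = Schedule("linear", k0, t_max=100.0) if k0 else None
    traj = run_protocol(mesh, params, schedule=schedule, t_end=100.0,
                        snapshot_every=None, seed=4,
                        kt1_edge_ref=E_REFERENCE)
    n_t1 = sum(1 for e in traj.events if e[1] == "t1")
    energy = traj.simulation._evaluate().energy
    results[label] = (reduced_volume(traj.final_mesh), energy, n_t1,
                      polygon_class_counts(traj.final_mesh))

for label, (v, w, n_t1, counts) in results.items():
    print(f"{label:8s}: v = {v:.3f}  energy = {w:.2f}  "
          f"T1 events = {n_t1}  polygon classes = {counts}")
print("active - passive final energy:",
      f"{results['active'][1] - results['passive'][1]:+.2f}",
      "(positive: the active shape is an out-of-equilibrium trap)")
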