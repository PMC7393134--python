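"""Snapshot and trajectory I/O.

Geometry is written as plain-text OFF files (one per surface, apical and
basal, sharing the face table) readable by standard mesh viewers, plus a
JSON sidecar with everything needed to resume a run bit-exactly: time,
parameters, junction tensions, rosette dwells, growth state and the exact
RNG states.  Positions are serialized with ``repr``, which round-trips
IEEE doubles exactly.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from . import energetics as en
from .dynamics import Schedule, Simulation, _Rosette
from .mesh import ShellMesh
from .rearrangements import T1Info

FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# OFF geometry


def write_off(path, positions: np.ndarray, faces) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(positions)} {len(faces)} 0\n")
        for p in positions:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        for loop in faces:
            fh.write(str(len(loop)) + " " + " ".join(str(v) for v in loop) + "\n")


def read_off(path):
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError(f"{path} is not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    k = 4
    pos = np.array(tokens[k:k + 3 * nv], dtype=float).reshape(nv, 3)
    k += 3 * nv
    faces = []
    for _ in range(nf):
        n = int(tokens[k])
        faces.append([int(x) for x in tokens[k + 1:k + 1 + n]])
        k += 1 + n
    return pos, faces


def save_mesh(mesh: ShellMesh, directory, prefix: str = "shell") -> None:
    """Write the two surfaces as OFF files (identical face tables)."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_off(d / f"{prefix}.apical.off", mesh.apical, mesh.cells)
    write_off(d / f"{prefix}.basal.off", mesh.basal, mesh.cells)


def load_mesh(directory, prefix: str = "shell", time: float = 0.0) -> ShellMesh:
    d = pathlib.Path(directory)
    apical, cells = read_off(d / f"{prefix}.apical.off")
    basal, cells_b = read_off(d / f"{prefix}.basal.off")
    if cells != cells_b:
        raise ValueError("apical and basal face tables differ")
    return ShellMesh(apical, basal, cells, time=time)


# --------------------------------------------------------------------------
# full simulation snapshots


def _rng_state(rng):
    return json.loads(json.dumps(rng.bit_generator.state))


def _restore_rng(state):
    rng = np.random.default_rng()
    rng.bit_generator.state = state
    return rng


def save_snapshot(sim: Simulation, directory, prefix: str = "snapshot") -> None:
    """Serialize a full simulation state (resume reproduces the continued
    trajectory bit-exactly)."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_mesh(sim.mesh, d, prefix)
    meta = {
        "format_version": FORMAT_VERSION,
        "time": sim.t,
        "step": sim.step,
        "dt": sim.dt,
        "scheme": sim.scheme,
        "tau": sim.tau,
        "delta_l": sim.delta_l,
        "trigger_length": sim.trigger_length,
        "schedule": dataclasses.asdict(sim.schedule) if sim.schedule else None,
        "params": {
            "alpha": sim.params.alpha,
            "beta": sim.params.beta,
            "v_lumen_target": sim.params.v_lumen_target,
            "k_cell": sim.params.k_cell,
            "k_lumen": sim.params.k_lumen,
        },
        "gamma": sim.junctions.gamma.tolist(),
        "refractory": sim.junctions.refractory.astype(int).tolist(),
        "vtargets": sim.vtargets.tolist(),
        "growing": sim.growing.astype(int).tolist(),
        "growth": sim.growth,
        "tau_g": sim.tau_g,
        "tau_d": sim.tau_d,
        "couple_lumen": sim.couple_lumen,
        "n_cells_stop": sim.n_cells_stop,
        "kt1_edge_ref": sim.kt1_edge_ref,
        "v_lumen": sim.v_lumen,
        "postponed": sorted(sim.postponed),
        "blocked_cells": sorted(sim.blocked_cells),
        "next_attempt": sim.next_attempt,
        "attempt_p": sim._attempt_p,
        "next_entry": sim.next_entry,
        "rosettes": [
            {"info": dataclasses.asdict(r.info), "expiry_step": r.expiry_step,
             "scheme": r.scheme, "pre_len": r.pre_len,
             "dir_apical": r.dir_apical.tolist(),
             "dir_basal": r.dir_basal.tolist()}
            for r in sim.rosettes],
        "rng": {
            "t1": _rng_state(sim.rng_t1),
            "ou": _rng_state(sim.rng_ou),
            "growth": _rng_state(sim.rng_growth),
        },
    }
    with open(d / f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_snapshot(directory, prefix: str = "snapshot") -> Simulation:
    d = pathlib.Path(directory)
    with open(d / f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"snapshot format version {meta.get('format_version')} "
            f"not supported (expected {FORMAT_VERSION})")
    mesh = load_mesh(d, prefix, time=meta["time"])
    params = en.ModelParams(**meta["params"])
    schedule = Schedule(**meta["schedule"]) if meta["schedule"] else None
    sim = Simulation(mesh, params, scheme=meta["scheme"], schedule=schedule,
                     dt=meta["dt"], tau=meta["tau"], delta_l=meta["delta_l"],
                     trigger_length=meta["trigger_length"],
                     growth=meta["growth"], tau_g=meta["tau_g"],
                     tau_d=meta["tau_d"], couple_lumen=meta["couple_lumen"],
                     n_cells_stop=meta["n_cells_stop"],
                     kt1_edge_ref=meta["kt1_edge_ref"])
    sim.step = meta["step"]
    sim.junctions.gamma = np.array(meta["gamma"], dtype=float)
    sim.junctions.refractory = np.array(meta["refractory"], dtype=bool)
    sim.vtargets = np.array(meta["vtargets"], dtype=float)
    sim.growing = np.array(meta["growing"], dtype=bool)
    sim.v_lumen = meta["v_lumen"]
    sim.postponed = set(meta["postponed"])
    sim.blocked_cells = set(meta["blocked_cells"])
    sim.next_attempt = meta["next_attempt"]
    sim._attempt_p = meta["attempt_p"]
    sim.next_entry = meta["next_entry"]
    sim.rosettes = [
        _Rosette(T1Info(**r["info"]), r["expiry_step"], r["scheme"],
                 r["pre_len"], np.array(r["dir_apical"]),
                 np.array(r["dir_basal"]))
        for r in meta["rosettes"]]
    sim.rng_t1 = _restore_rng(meta["rng"]["t1"])
    sim.rng_ou = _restore_rng(meta["rng"]["ou"])
    sim.rng_growth = _restore_rng(meta["rng"]["growth"])
    return sim


# --------------------------------------------------------------------------
# logs


def write_energy_log(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("t,w_surface,w_constraint,w_line,total\n")
        for row in rows:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def write_event_log(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("t,kind,data1,data2,data3\n")
        for row in rows:
            padded = list(row) + [""] * (5 - len(row))
            fh.write(",".join(str(x) for x in padded) + "\n")
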