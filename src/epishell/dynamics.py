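"""Overdamped time integration, activity schedules and run protocols.

Vertices follow pure gradient descent, dr/dt = -grad w, integrated with a
forward-Euler step of dt = 1e-4 (time in units of the intrinsic relaxation
time, the inverse of lateral tension times vertex mobility).  Between
Euler steps the driver handles the discrete events: T1 initiations
(threshold or fluctuating-tension scheme), rosette dwells and resolutions,
and — in growing shells — growth-phase entries and cell divisions.

The hot loop runs in a jit kernel over chunks of steps; the chunk
boundaries are determined only by the dynamics events themselves, so a
trajectory is bit-reproducible given the seed and parameters.  Stochastic
T1 attempts are scheduled by exact geometric waiting times with thinning
(the attempt rate k_T1(t) dt never increases along our schedules), which
is equivalent to the per-step, per-junction Bernoulli trial at rate
k_T1 dt / E.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import energetics as en
from ._kernel import run_steps
from .mesh import ShellMesh
from .rearrangements import (DELTA_L, DWELL_TIME, OU_TAU, SEPARATION,
                             TRIGGER_LENGTH, JunctionState, T1Info,
                             collapse_junction, resolve_t1, t1_info, t1_legal)

DT = 1e-4
_MAX_CHUNK = 4000


class SimulationError(RuntimeError):
    """Raised when the dynamics produce a non-finite energy."""


@dataclasses.dataclass
class Schedule:
    """Temporal profile of the activity parameter (k_T1 or sigma).

    linear : v0 * (t_max - t) / t_max, clipped at zero
    step   : v0 for t < switch_time (default t_max / 2), then zero
    constant : v0 throughout
    """

    kind: str
    v0: float
    t_max: float = 1000.0
    switch_time: float | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "step", "constant"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.v0 < 0:
            raise ValueError("activity level must be nonnegative")

    def value(self, t: float) -> float:
        if self.kind == "constant":
            return self.v0
        if self.kind == "linear":
            return self.v0 * max(self.t_max - t, 0.0) / self.t_max
        sw = self.t_max / 2.0 if self.switch_time is None else self.switch_time
        return self.v0 if t < sw else 0.0


def schedule_value(schedule: Schedule | None, t: float) -> float:
    return 0.0 if schedule is None else schedule.value(t)


@dataclasses.dataclass
class _Rosette:
    info: T1Info
    expiry_step: int
    scheme: str
    pre_len: float
    dir_apical: np.ndarray
    dir_basal: np.ndarray


@dataclasses.dataclass
class Trajectory:
    """Snapshots plus energy and event logs of one run."""

    times: list
    meshes: list
    energy: list          # rows (t, w_surface, w_constraint, w_line, total)
    events: list          # rows (t, kind, *data)
    final_mesh: ShellMesh
    simulation: "Simulation"


class Simulation:
    """Mutable simulation state and the chunked advance loop.

    scheme : "threshold" (active T1 rate from ``schedule``) or
        "fluctuation" (OU line tensions of magnitude ``schedule``).
    growth : enable stochastic growth-phase entry, linear target-volume
        growth and division; ``couple_lumen`` makes the preferred lumen
        volume track the total tissue target volume.
    """

    def __init__(self, mesh: ShellMesh, params: en.ModelParams, *,
                 scheme: str = "threshold", schedule: Schedule | None = None,
                 dt: float = DT, seed: int = 0, tau: float = OU_TAU,
                 delta_l: float = DELTA_L, trigger_length: float = TRIGGER_LENGTH,
                 growth: bool = False, tau_g: float = 1.0, tau_d: float = 2000.0,
                 couple_lumen: bool = False, n_cells_stop: int | None = None,
                 kt1_edge_ref: int | None = None):
        if scheme not in ("threshold", "fluctuation"):
            raise ValueError(f"unknown activity scheme {scheme!r}")
        self.mesh = mesh
        self.params = params
        self.scheme = scheme
        self.schedule = schedule
        self.dt = float(dt)
        self.tau = tau
        self.delta_l = delta_l
        self.trigger_length = trigger_length
        self.step = int(round(mesh.time / dt))
        self.junctions = JunctionState.zeros(mesh.n_junctions)
        if params.line_tensions is not None:
            self.junctions.gamma[:] = params.line_tensions
        self.rosettes: list[_Rosette] = []
        self.blocked_cells: set[int] = set()
        self.events: list = []
        self.energy_log: list = []
        ss = np.random.SeedSequence(seed)
        s_t1, s_ou, s_growth = ss.spawn(3)
        self.rng_t1 = np.random.default_rng(s_t1)
        self.rng_ou = np.random.default_rng(s_ou)
        self.rng_growth = np.random.default_rng(s_growth)
        self.next_attempt: int | None = None
        self._attempt_p = 0.0
        self.kt1_edge_ref = kt1_edge_ref
        # growth state
        self.growth = growth
        self.tau_g, self.tau_d = tau_g, tau_d
        self.couple_lumen = couple_lumen
        self.n_cells_stop = n_cells_stop
        self.vtargets = params.vtargets(mesh.n_cells).copy()
        self.growing = np.zeros(mesh.n_cells, dtype=bool)
        self.postponed: set[int] = set()
        self.next_entry: int | None = None
        self.v_lumen = float(params.v_lumen_target)
        if growth and couple_lumen:
            from .growth import lumen_target
            self.v_lumen = lumen_target(self.vtargets.sum())

    # -- time bookkeeping --------------------------------------------------

    @property
    def t(self) -> float:
        return self.step * self.dt

    @property
    def dwell_steps(self) -> int:
        return max(1, int(round(DWELL_TIME / self.dt)))

    def _threshold(self) -> float:
        return self.delta_l if self.scheme == "threshold" else self.trigger_length

    # -- event scheduling --------------------------------------------------

    def _kt1_eff(self, t: float) -> float:
        """Active T1 rate, optionally rescaled by the junction count so the
        per-junction rate matches a reference shell (k -> k E / E_ref)."""
        k = schedule_value(self.schedule, t)
        if self.kt1_edge_ref:
            k *= self.mesh.n_junctions / self.kt1_edge_ref
        return k

    def _sample_attempt(self):
        """Next stochastic active-T1 attempt (threshold scheme only)."""
        if self.scheme != "threshold" or self.schedule is None:
            self.next_attempt = None
            return
        p = self._kt1_eff(self.t) * self.dt
        if p <= 0.0:
            self.next_attempt = None
            return
        p = min(p, 1.0)
        self._attempt_p = p
        self.next_attempt = self.step + int(self.rng_t1.geometric(p))

    def _sample_entry(self):
        """Next growth-phase entry event."""
        if not self.growth:
            self.next_entry = None
            return
        n_q = int((~self.growing).sum())
        if n_q == 0:
            self.next_entry = None
            return
        p = min(n_q * self.dt / self.tau_d, 1.0)
        self.next_entry = self.step + int(self.rng_growth.geometric(p))

    # -- T1 machinery ------------------------------------------------------

    def _initiate_t1(self, junction: int, scheme_label: str) -> bool:
        if not t1_legal(self.mesh, junction, self.blocked_cells):
            self.junctions.refractory[junction] = True
            return False
        info = t1_info(self.mesh, junction)
        pre_len, da, db = collapse_junction(self.mesh, junction)
        self.rosettes.append(_Rosette(info, self.step + self.dwell_steps,
                                      scheme_label, pre_len, da, db))
        self.blocked_cells |= {info.cell_l, info.cell_r,
                               info.cell_a, info.cell_b}
        self.junctions.refractory[junction] = True
        self.events.append((self.t, "t1", scheme_label, junction, pre_len))
        return True

    def _resolve_rosette(self, ros: _Rosette):
        old_ec = self.mesh.topology.edge_cells.copy()
        resolve_t1(self.mesh, ros.info, ros.dir_apical, ros.dir_basal,
                   SEPARATION)
        self.junctions.remap(old_ec, self.mesh.topology.edge_cells,
                             fresh_pairs=[(ros.info.cell_a, ros.info.cell_b)])
        self.blocked_cells -= {ros.info.cell_l, ros.info.cell_r,
                               ros.info.cell_a, ros.info.cell_b}
        self.rosettes.remove(ros)
        if self.postponed:
            self._retry_postponed()

    # -- growth machinery --------------------------------------------------

    def _enter_growth(self):
        quiescent = np.nonzero(~self.growing)[0]
        if len(quiescent) == 0:
            return
        c = int(quiescent[self.rng_growth.integers(len(quiescent))])
        self.growing[c] = True
        self.events.append((self.t, "growth_entry", c))

    def _divide_due_cells(self):
        from .growth import divide_cell
        due = np.nonzero(self.vtargets >= 2.0)[0]
        for c in due:
            if len(self.mesh.cells[c]) < 4 or c in self.blocked_cells:
                self.postponed.add(int(c))
                self.growing[c] = False      # paused at doubled volume
                continue
            self._do_division(int(c), divide_cell)
        self._sample_entry()

    def _retry_postponed(self):
        from .growth import divide_cell
        for c in sorted(self.postponed):
            if len(self.mesh.cells[c]) >= 4 and c not in self.blocked_cells:
                self.postponed.discard(c)
                self._do_division(c, divide_cell)

    def _do_division(self, c: int, divide_cell):
        old_ec = self.mesh.topology.edge_cells.copy()
        new_id = divide_cell(self.mesh, c, self.rng_growth)
        self.junctions.remap(old_ec, self.mesh.topology.edge_cells)
        self.vtargets[c] = 1.0
        self.vtargets = np.append(self.vtargets, 1.0)
        self.growing[c] = False
        self.growing = np.append(self.growing, False)
        self.events.append((self.t, "division", c, new_id))
        if self.kt1_edge_ref:
            self._sample_attempt()   # junction count changed

    # -- lumen target ------------------------------------------------------

    def _vlumen_array(self, n: int) -> np.ndarray:
        if not (self.growth and self.couple_lumen):
            return np.full(n, self.v_lumen)
        from .growth import lumen_target_array
        slope = self.growing.sum() * self.dt / self.tau_g
        tissue = self.vtargets.sum() + slope * np.arange(1, n + 1)
        return lumen_target_array(tissue, v_init=self.v_lumen)

    # -- main loop ---------------------------------------------------------

    def _junction_mask(self) -> np.ndarray:
        mask = self.junctions.refractory.astype(np.uint8)
        if self.blocked_cells:
            topo = self.mesh.topology
            blocked = np.zeros(self.mesh.n_cells, dtype=bool)
            blocked[list(self.blocked_cells)] = True
            mask |= (blocked[topo.edge_l] | blocked[topo.edge_r]).astype(np.uint8)
        return mask

    def _pairs(self):
        if not self.rosettes:
            return (np.empty(0, dtype=np.int32),) * 2
        u = np.array([r.info.u for r in self.rosettes], dtype=np.int32)
        v = np.array([r.info.v for r in self.rosettes], dtype=np.int32)
        return u, v

    def advance(self, t_end: float, *, log_every: float | None = None,
                snapshot_every: float | None = None, trajectory=None):
        """Advance to ``t_end``, appending to ``trajectory`` if given."""
        n_end = int(round(t_end / self.dt))
        if self.next_attempt is None:
            self._sample_attempt()
        if self.growth and self.next_entry is None:
            self._sample_entry()
        next_log = None if log_every is None else self.t
        next_snap = None if snapshot_every is None else self.t
        while self.step < n_end:
            # discrete events due now
            for ros in [r for r in self.rosettes if r.expiry_step <= self.step]:
                self._resolve_rosette(ros)
            if self.next_attempt is not None and self.next_attempt <= self.step:
                k_now = self._kt1_eff(self.t) * self.dt
                if self.rng_t1.random() < k_now / self._attempt_p:
                    j = int(self.rng_t1.integers(self.mesh.n_junctions))
                    self._initiate_t1(j, "active")
                self._sample_attempt()
            if self.next_entry is not None and self.next_entry <= self.step:
                self._enter_growth()
                self._sample_entry()
            if self.n_cells_stop is not None and self.mesh.n_cells >= self.n_cells_stop:
                break
            # logging
            if next_log is not None and self.t >= next_log:
                self._log_energy()
                next_log += log_every
            if next_snap is not None and trajectory is not None and self.t >= next_snap:
                trajectory.times.append(self.t)
                trajectory.meshes.append(self.mesh.copy())
                next_snap += snapshot_every
            # assemble chunk
            n = min(_MAX_CHUNK, n_end - self.step)
            for ros in self.rosettes:
                n = min(n, ros.expiry_step - self.step)
            if self.next_attempt is not None:
                n = min(n, self.next_attempt - self.step)
            if self.next_entry is not None:
                n = min(n, self.next_entry - self.step)
            if next_log is not None:
                n = min(n, int(np.ceil((next_log - self.t) / self.dt)))
            if next_snap is not None:
                n = min(n, int(np.ceil((next_snap - self.t) / self.dt)))
            if n <= 0:
                continue
            n = int(n)
            done, trig, status = self._run_chunk(n)
            self.step += done
            if status == 1:
                self._initiate_t1(int(trig), "passive" if self.scheme == "threshold"
                                  else "fluctuation")
            elif status == 2:
                raise SimulationError(
                    f"non-finite energy at t={self.t:.4f}")
            elif status == 3:
                self._divide_due_cells()
        for ros in [r for r in self.rosettes if r.expiry_step <= self.step]:
            self._resolve_rosette(ros)
        if next_log is not None:
            self._log_energy()
        if next_snap is not None and trajectory is not None:
            trajectory.times.append(self.t)
            trajectory.meshes.append(self.mesh.copy())
        self.mesh.time = self.t
        return self

    def _run_chunk(self, n: int):
        topo = self.mesh.topology
        ne = topo.edges.shape[0]
        mask = self._junction_mask()
        pair_u, pair_v = self._pairs()
        ou = self.scheme == "fluctuation" and self.schedule is not None
        if ou:
            tt = self.t + np.arange(n) * self.dt
            sig = np.array([schedule_value(self.schedule, x) for x in tt])
            amp = np.sqrt(2.0 * sig ** 2 * self.dt / self.tau)
            noise = self.rng_ou.standard_normal((n, ne))
        else:
            amp = np.zeros(1)
            noise = np.zeros((1, 1))
        inc = np.where(self.growing, self.dt / self.tau_g, 0.0) \
            if self.growth else np.zeros(self.mesh.n_cells)
        vlumen_arr = self._vlumen_array(n)
        done, trig, status = run_steps(
            self.mesh.apical, self.mesh.basal,
            topo.cells_flat, topo.cells_off,
            topo.edge_u, topo.edge_v, topo.edge_l, topo.edge_r,
            self.junctions.gamma, self.vtargets,
            float(self.params.alpha), float(self.params.beta),
            float(self.params.k_cell), float(self.params.k_lumen),
            vlumen_arr,
            self.dt, n, self._threshold(), mask,
            pair_u, pair_v,
            ou, self.dt / self.tau, amp, noise,
            self.growth, inc)
        # kernel clears mask bits of junctions that regrew; propagate to the
        # refractory flags (dwell blocks live in blocked_cells, not here)
        self.junctions.refractory &= mask.astype(bool)
        if self.growth and self.couple_lumen and done > 0:
            self.v_lumen = float(vlumen_arr[done - 1])
        return done, trig, status

    def _log_energy(self):
        rep = self._evaluate()
        self.energy_log.append((self.t, rep.w_surface, rep.w_constraint,
                                rep.w_line, rep.energy))

    def _evaluate(self) -> en.EnergyReport:
        p = dataclasses.replace(self.params,
                                cell_volume_targets=self.vtargets,
                                line_tensions=self.junctions.gamma,
                                v_lumen_target=self.v_lumen)
        return en.evaluate(self.mesh, p)

    def euler_step(self):
        """One explicit Euler step (no T1 handling); mainly for tests."""
        rep = self._evaluate()
        if not np.isfinite(rep.energy):
            raise SimulationError(f"non-finite energy at t={self.t:.4f}")
        self.mesh.apical += self.dt * rep.force_apical
        self.mesh.basal += self.dt * rep.force_basal
        for u, v in zip(*self._pairs()):
            self.mesh.apical[[u, v]] = self.mesh.apical[[u, v]].mean(axis=0)
            self.mesh.basal[[u, v]] = self.mesh.basal[[u, v]].mean(axis=0)
        self.step += 1
        self.mesh.time = self.t
        return self


# --------------------------------------------------------------------------
# protocols


def default_duration(schedule: Schedule | None) -> float:
    """Run length when none is given: 1000 for active runs, 2000 for
    passive ones (stomatocytes at alpha ~ beta develop slowly)."""
    return 2000.0 if schedule is None or schedule.v0 == 0 else 1000.0


def run_protocol(mesh: ShellMesh, params: en.ModelParams, *,
                 schedule: Schedule | None = None, scheme: str = "threshold",
                 t_end: float | None = None, seed: int = 0, dt: float = DT,
                 snapshot_every: float | None = 10.0, log_every: float = 1.0,
                 tau: float = OU_TAU, kt1_edge_ref: int | None = None) -> Trajectory:
    """Standard fixed-cell-number protocol.

    Alternates Euler steps with rearrangement handling.  Default duration:
    1000 for active runs, 2000 for passive runs (slow stomatocyte
    development needs the longer relaxation).
    """
    if t_end is None:
        t_end = default_duration(schedule)
    sim = Simulation(mesh, params, scheme=scheme, schedule=schedule,
                     dt=dt, seed=seed, tau=tau, kt1_edge_ref=kt1_edge_ref)
    traj = Trajectory([], [], sim.energy_log, sim.events, mesh, sim)
    sim.advance(t_end, log_every=log_every, snapshot_every=snapshot_every,
                trajectory=traj)
    traj.final_mesh = sim.mesh
    return traj


def relax(mesh: ShellMesh, v_lumen: float, params: en.ModelParams | None = None,
          t_end: float = 1.0, dt: float = DT, seed: int = 0) -> ShellMesh:
    """Short passive relaxation (no active T1s) used after seeding."""
    if params is None:
        params = en.ModelParams(alpha=1.0, beta=1.0, v_lumen_target=v_lumen)
    sim = Simulation(mesh, params, scheme="threshold", schedule=None,
                     dt=dt, seed=seed)
    sim.advance(mesh.time + t_end)
    return sim.mesh
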