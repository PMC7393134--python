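"""Run configuration and the phase-diagram sweep driver.

A :class:`RunConfig` captures every knob of a single simulation (all
defaults are the reference study conditions) and round-trips losslessly
through YAML.  :func:`run_from_config` builds the initial shell, applies
the cell-number rescalings of the active T1 rate (k -> k E / E_300) and of
the preferred lumen volume (size-matching rule) when the shell is not the
300-cell reference, runs the protocol and returns the trajectory.
"""

from __future__ import annotations

import csv
import dataclasses
import pathlib

import yaml

from . import energetics as en
from . import morphometrics as mm
from .dynamics import Schedule, Trajectory, run_protocol
from .growth import lumen_target
from .seeding import SeedSpec, build_initial_shell

#: junction count of the reference 300-cell shell, E = 3 (N_c - 2)
E_REFERENCE = 894
N_REFERENCE = 300


@dataclasses.dataclass
class RunConfig:
    """Complete description of one fixed-cell-number run."""

    alpha: float = 1.0
    beta: float = 1.0
    n_cells: int = N_REFERENCE
    v_lumen: float | None = None        # None: size-matching rule
    scheme: str = "threshold"           # threshold | fluctuation
    schedule_kind: str = "linear"       # linear | step | constant
    k_t1: float = 0.0                   # initial active T1 rate (reference units)
    sigma: float = 0.0                  # initial OU tension magnitude
    t_max: float = 1000.0               # schedule duration
    switch_time: float | None = None    # step schedule switch (default t_max/2)
    t_end: float | None = None          # None: 1000 active, 2000 passive
    dt: float = 1e-4
    seed: int = 0
    k_cell: float = 100.0
    k_lumen: float = 100.0
    prerelax_time: float = 1.0
    snapshot_every: float | None = 10.0
    log_every: float = 1.0
    rescale_kt1: bool = True

    def resolved_v_lumen(self) -> float:
        if self.v_lumen is not None:
            return self.v_lumen
        return lumen_target(self.n_cells)

    def activity(self) -> float:
        return self.sigma if self.scheme == "fluctuation" else self.k_t1

    def build_schedule(self) -> Schedule | None:
        v0 = self.activity()
        if v0 <= 0:
            return None
        return Schedule(self.schedule_kind, v0, t_max=self.t_max,
                        switch_time=self.switch_time)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def run_from_config(config: RunConfig) -> Trajectory:
    """Build, pre-relax and run a shell according to ``config``."""
    v_lumen = config.resolved_v_lumen()
    params = en.ModelParams(alpha=config.alpha, beta=config.beta,
                            v_lumen_target=v_lumen,
                            k_cell=config.k_cell, k_lumen=config.k_lumen)
    spec = SeedSpec(config.n_cells, v_lumen, seed=config.seed,
                    prerelax_time=config.prerelax_time)
    mesh = build_initial_shell(spec, params=params)
    mesh.time = 0.0
    schedule = config.build_schedule()
    kwargs = {}
    if (config.rescale_kt1 and config.scheme == "threshold"
            and config.n_cells != N_REFERENCE):
        kwargs["kt1_edge_ref"] = E_REFERENCE
    return run_protocol(mesh, params, schedule=schedule, scheme=config.scheme,
                        t_end=config.t_end, seed=config.seed, dt=config.dt,
                        snapshot_every=config.snapshot_every,
                        log_every=config.log_every, **kwargs)


def run_protocol_rescaled(mesh, params, **kwargs):
    """run_protocol with the reference-shell k_T1 rescaling applied."""
    return run_protocol(mesh, params, kt1_edge_ref=E_REFERENCE, **kwargs)


# --------------------------------------------------------------------------
# sweep driver


def sweep(alphas, betas, *, replicates: int = 1, out_csv=None,
          config: RunConfig | None = None, progress=None) -> list:
    """Run a grid of (alpha, beta) pairs and classify the final shapes.

    Returns rows (alpha, beta, replicate, v, delta, label, energy); run
    failures are recorded with label "error" and the sweep continues.
    """
    base = config or RunConfig()
    rows = []
    for a in alphas:
        for b in betas:
            for r in range(replicates):
                cfg = dataclasses.replace(base, alpha=a, beta=b,
                                          seed=base.seed + r)
                try:
                    traj = run_from_config(cfg)
                    rep = mm.analyze(traj.final_mesh, alpha=a, beta=b)
                    energy = traj.simulation._evaluate().energy
                    row = (a, b, r, rep.v, rep.delta, rep.label, energy)
                except Exception as exc:          # keep sweeping
                    row = (a, b, r, float("nan"), float("nan"),
                           "error", float("nan"))
                    if progress:
                        progress(f"run ({a}, {b}, {r}) failed: {exc}")
                rows.append(row)
                if progress:
                    progress(f"({a}, {b}, rep {r}) -> {row[5]} v={row[3]:.3f}")
    if out_csv is not None:
        path = pathlib.Path(out_csv)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["alpha", "beta", "replicate", "v", "delta",
                        "label", "energy"])
            w.writerows(rows)
    return rows
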