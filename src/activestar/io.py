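"""Plain-text trajectory and configuration I/O.

Two trajectory dialects are supported, both line-based text:

* XYZ-with-velocities: per frame ``n`` / comment (carries ``time=``) /
  ``A x y z vx vy vz`` per bead.
* LAMMPS dump: ``ITEM: TIMESTEP / NUMBER OF ATOMS / BOX BOUNDS / ATOMS
  <columns>`` with at least ``id x y z``; ``vx vy vz`` and ``type`` are
  honoured, and the column order is taken from the ATOMS header line.

Configs are YAML with ``topology``, ``activity``, ``forcefield`` and
``run`` blocks; the activity block accepts either an explicit ``kBT`` or a
``ratio`` (f_a/(kBT)) resolved at fixed f_a.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import yaml

from .activity import ActivityParams, kBT_for_ratio
from .forcefield import ForceFieldParams
from .integrator import SimulationParams
from .topology import StarTopology, SystemState, build_chain, build_star

__all__ = [
    "write_xyz_frame",
    "read_xyz",
    "DumpWriter",
    "read_lammps_dump",
    "topology_to_json",
    "topology_from_json",
    "load_config",
    "save_config",
    "params_from_dict",
]


# ---------------------------------------------------------------- XYZ

def write_xyz_frame(fh, state: SystemState, element: str = "A") -> None:
    """Append one frame (positions + velocities) to an open text handle."""
    n = len(state.positions)
    fh.write(f"{n}\n")
    fh.write(f"time={state.time:.10g}\n")
    for (x, y, z), (vx, vy, vz) in zip(state.positions, state.velocities):
        fh.write(f"{element} {x:.10g} {y:.10g} {z:.10g} {vx:.10g} {vy:.10g} {vz:.10g}\n")


def read_xyz(path) -> list[SystemState]:
    """Read all frames of an XYZ(-with-velocities) file."""
    frames = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            comment = fh.readline()
            t = 0.0
            for tok in comment.split():
                if tok.startswith("time="):
                    t = float(tok[5:])
            pos = np.zeros((n, 3))
            vel = np.zeros((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(v) for v in parts[1:4]]
                if len(parts) >= 7:
                    vel[i] = [float(v) for v in parts[4:7]]
            frames.append(SystemState(pos, vel, time=t))
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


# ---------------------------------------------------------------- LAMMPS dump

class DumpWriter:
    """Streams frames to a LAMMPS-dump text file (id type x y z vx vy vz).

    Usable directly as a :func:`activestar.integrator.run` observer.
    """

    def __init__(self, path, dt: float = 1.0):
        self._fh = open(path, "w")
        self._dt = dt

    def __call__(self, step_index: int, state: SystemState) -> None:
        self.write(state, step_index)

    def write(self, state: SystemState, timestep: int) -> None:
        pos, vel = state.positions, state.velocities
        lo, hi = float(pos.min()) - 1.0, float(pos.max()) + 1.0
        fh = self._fh
        fh.write("ITEM: TIMESTEP\n%d\n" % timestep)
        fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(pos))
        fh.write("ITEM: BOX BOUNDS ff ff ff\n")
        for _ in range(3):
            fh.write(f"{lo:.10g} {hi:.10g}\n")
        fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
        for i in range(len(pos)):
            x, y, z = pos[i]
            vx, vy, vz = vel[i]
            fh.write(f"{i + 1} 1 {x:.10g} {y:.10g} {z:.10g} {vx:.10g} {vy:.10g} {vz:.10g}\n")

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_lammps_dump(path, dt: float = 1.0) -> list[SystemState]:
    """Read a LAMMPS dump; any per-atom column order declared in the
    ``ITEM: ATOMS`` header is accepted.  ``time = timestep * dt``."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        timestep = int(lines[i + 1])
        assert lines[i + 2].startswith("ITEM: NUMBER OF ATOMS")
        n = int(lines[i + 3])
        j = i + 4
        while not lines[j].startswith("ITEM: ATOMS"):
            j += 1
        cols = lines[j].split()[2:]
        idx = {c: k for k, c in enumerate(cols)}
        for c in ("id", "x", "y", "z"):
            if c not in idx:
                raise ValueError(f"dump misses required column {c!r}")
        pos = np.zeros((n, 3))
        vel = np.zeros((n, 3))
        for row in lines[j + 1 : j + 1 + n]:
            parts = row.split()
            a = int(parts[idx["id"]]) - 1
            pos[a] = [float(parts[idx[c]]) for c in "xyz"]
            if "vx" in idx:
                vel[a] = [float(parts[idx[c]]) for c in ("vx", "vy", "vz")]
        frames.append(SystemState(pos, vel, time=timestep * dt))
        i = j + 1 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


# ---------------------------------------------------------------- topology json

def topology_to_json(topology: StarTopology) -> str:
    return json.dumps(
        {
            "n_arms": topology.n_arms,
            "arm_lengths": list(topology.arm_lengths),
        }
    )


def topology_from_json(text: str) -> StarTopology:
    d = json.loads(text)
    lengths = d.get("arm_lengths")
    if lengths and len(set(lengths)) == 1:
        return build_star(d["n_arms"], lengths[0])
    if lengths and len(lengths) == 2:
        return build_chain(sum(lengths) + 1)
    if "arm_length" in d:
        return build_star(d["n_arms"], d["arm_length"])
    raise ValueError("unrecognised topology JSON")


# ---------------------------------------------------------------- config

def params_from_dict(cfg: dict) -> tuple[StarTopology, SimulationParams]:
    """Build (topology, SimulationParams) from a nested config dict."""
    topo_cfg = dict(cfg.get("topology", {}))
    if "n_beads" in topo_cfg:
        topology = build_chain(topo_cfg["n_beads"])
    else:
        topology = build_star(topo_cfg.get("n_arms", 3), topo_cfg.get("arm_length", 10))

    act_cfg = dict(cfg.get("activity", {}))
    if "ratio" in act_cfg:
        ratio = act_cfg.pop("ratio")
        act_cfg.setdefault("fa", 1.0)
        if ratio == 0:
            act_cfg.update(model="passive", fa=0.0, kBT=1.0)
        else:
            act_cfg["kBT"] = kBT_for_ratio(ratio, act_cfg["fa"])
    activity = ActivityParams(**act_cfg)

    ff = ForceFieldParams(**cfg.get("forcefield", {}))
    run_cfg = dict(cfg.get("run", {}))
    return topology, SimulationParams(activity=activity, forcefield=ff, **run_cfg)


def load_config(path) -> tuple[StarTopology, SimulationParams]:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def save_config(path, topology: StarTopology, params: SimulationParams) -> None:
    cfg = {
        "topology": {
            "n_arms": topology.n_arms,
            "arm_length": topology.arm_lengths[0],
        }
        if len(set(topology.arm_lengths)) == 1
        else {"n_beads": topology.n_beads},
        "activity": asdict(params.activity),
        "forcefield": asdict(params.forcefield),
        "run": {
            "mass": params.mass,
            "gamma": params.gamma,
            "dt": params.dt,
            "n_steps": params.n_steps,
            "sample_every": params.sample_every,
            "seed": params.seed,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
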