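"""Underdamped Langevin dynamics of the full bead-spring molecule.

Equation of motion per bead (reduced units):

    m r''_i + gamma r'_i = -grad U(r) + F^a_i + F^r_i

with U the bond + WCA potential, F^a the active force of the selected model
and F^r Gaussian white noise obeying the fluctuation-dissipation theorem
<F^r_i(t) . F^r_j(t')> = 6 kBT gamma delta_ij delta(t - t').  Time stepping
is velocity-Verlet with one force evaluation per step; friction and random
force enter every evaluation alongside the conservative and active terms
(the convention of common MD Langevin thermostats).  The molecule is a
single chain/star in open, unbounded space; positions stay unwrapped and
centre-of-mass motion is itself an observable.

:func:`step` is a plain-numpy reference single step; :func:`run` drives the
compiled kernel in chunks of ``sample_every`` steps, invoking observers and
accumulating observable series without holding frames in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .activity import (
    ActivityParams,
    abp_active_forces,
    abp_update_orientations,
    random_orientations,
    va_active_forces,
)
from .forcefield import ForceFieldParams, bond_energy_forces, wca_energy_forces
from .topology import StarTopology, SystemState, initial_conformation

__all__ = [
    "SimulationParams",
    "Trajectory",
    "Checkpoint",
    "default_dt",
    "random_forces",
    "step",
    "run",
]

DT_MAX = 1.0e-3

_MODEL_CODE = {
    "passive": _kernels.PASSIVE,
    "abp": _kernels.ABP,
    "velocity_aligned": _kernels.VELOCITY_ALIGNED,
}


def default_dt(ratio: float) -> float:
    """Timestep heuristic: 1e-3 up to f_a/(kBT) = 150, 5e-4 above.

    Higher activity means faster, stiffer effective dynamics, so the sweep
    uses the smaller step there.
    """
    return 1.0e-3 if ratio <= 150.0 else 5.0e-4


@dataclass(frozen=True)
class SimulationParams:
    """All physical and numerical constants of one run.

    mass, gamma : bead mass and translational friction (both 1 in the
        reference parameterisation).
    dt : timestep; capped at 1e-3 unless ``enforce_dt_max`` is disabled.
    n_steps, sample_every : run length and observable stride (steps).
    seed : master RNG seed for the whole run.
    activity : activity model block (also carries kBT — the single source
        of the temperature).
    forcefield : bond/WCA constants.
    """

    activity: ActivityParams = field(default_factory=ActivityParams)
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    mass: float = 1.0
    gamma: float = 1.0
    dt: float = 1.0e-3
    n_steps: int = 1000
    sample_every: int = 100
    seed: int = 0
    enforce_dt_max: bool = True

    def __post_init__(self):
        if self.mass <= 0 or self.gamma <= 0:
            raise ValueError("mass and gamma must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.enforce_dt_max and self.dt > DT_MAX:
            raise ValueError(
                f"dt = {self.dt} exceeds the {DT_MAX} cap; pass "
                "enforce_dt_max=False to override"
            )
        if self.n_steps < 0 or self.sample_every < 1:
            raise ValueError("n_steps must be >= 0 and sample_every >= 1")

    @property
    def kBT(self) -> float:
        return self.activity.kBT


@dataclass
class Trajectory:
    """Observable series sampled every ``sample_every`` steps, plus the end state.

    ``order_global``/``order_per_arm`` are NaN on frames where every bead is
    slower than the activity ``v_floor`` (order parameter undefined).
    Frames (positions+velocities) are kept only when requested.
    """

    times: np.ndarray
    rg: np.ndarray
    order_global: np.ndarray
    order_per_arm: np.ndarray
    com: np.ndarray
    kinetic_per_bead: np.ndarray
    final_state: SystemState
    frames: list | None = None

    def __len__(self):
        return len(self.times)


@dataclass
class Checkpoint:
    """Everything needed to continue a run bit-for-bit at a chunk boundary."""

    state: SystemState
    force: np.ndarray
    chunk_index: int
    steps_done: int


def random_forces(
    n_beads: int, kBT: float, gamma: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the discretised Langevin random force.

    Each Cartesian component is i.i.d. Gaussian with zero mean and variance
    2 kBT gamma / dt: the 6 kBT gamma of the 3D fluctuation-dissipation
    relation splits into 2 kBT gamma per component, and the delta correlation
    becomes 1/dt on a grid of step dt.
    """
    if kBT < 0:
        raise ValueError("kBT must be >= 0")
    if kBT == 0:
        return np.zeros((n_beads, 3))
    return rng.normal(scale=np.sqrt(2.0 * kBT * gamma / dt), size=(n_beads, 3))


def _total_force(state, params, topology, rng):
    ff, act = params.forcefield, params.activity
    _, f = bond_energy_forces(state, topology, ff)
    _, fw = wca_energy_forces(state, ff, topology)
    f += fw
    if act.model == "abp":
        f += abp_active_forces(state.orientations, act.fa)
    elif act.model == "velocity_aligned":
        f += va_active_forces(state.velocities, act.fa, act.v_floor)
    f -= params.gamma * state.velocities
    f += random_forces(topology.n_beads, act.kBT, params.gamma, params.dt, rng)
    return f


def step(
    state: SystemState,
    params: SimulationParams,
    topology: StarTopology,
    rng: np.random.Generator,
) -> SystemState:
    """One velocity-Verlet Langevin step (reference implementation).

    Evaluates the total force at entry and once after the drift, so a
    sequence of calls performs two evaluations per step where the compiled
    path performs one; statistically equivalent, not bitwise.  Raises on
    non-finite output.
    """
    s = state.copy()
    act = params.activity
    f = _total_force(s, params, topology, rng)
    half = 0.5 * params.dt / params.mass
    s.velocities += half * f
    s.positions += params.dt * s.velocities
    if act.model == "abp":
        s.orientations = abp_update_orientations(s.orientations, params.dt, act.Dr, rng)
    f = _total_force(s, params, topology, rng)
    s.velocities += half * f
    s.time += params.dt
    if not (np.isfinite(s.positions).all() and np.isfinite(s.velocities).all()):
        bead = int(np.argmax(~np.isfinite(s.positions).all(axis=1)))
        raise FloatingPointError(f"non-finite state at bead {bead}")
    return s


def _chunk_seeds(seed: int, n_chunks: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_chunks, dtype=np.uint32)


def run(
    params: SimulationParams,
    topology: StarTopology,
    state: SystemState | None = None,
    observers: tuple = (),
    store_frames: bool = False,
    restart: Checkpoint | None = None,
) -> tuple[Trajectory, Checkpoint]:
    """Integrate ``params.n_steps`` steps; sample observables every
    ``params.sample_every`` steps.

    Observables (time, Rg, velocity-bond order parameter global and per arm,
    centre of mass, mean kinetic energy per bead) are accumulated as small
    series; each ``observer(step_index, state)`` is also invoked at every
    sample so callers can stream frames to a trajectory sink.  Returns the
    trajectory and a :class:`Checkpoint`; passing the checkpoint back via
    ``restart`` continues the identical realisation.

    If ``state`` is None, a fresh conformation is built from the run seed.
    """
    from .analysis import order_parameter, radius_of_gyration

    act, ff = params.activity, params.forcefield
    if restart is not None:
        s = restart.state.copy()
        force = restart.force.copy()
        first_chunk = restart.chunk_index
        init_forces = False
    else:
        if state is None:
            state = initial_conformation(
                topology, bond_length=ff.l0, seed=params.seed,
                kBT=act.kBT if act.kBT > 0 else 1.0, mass=params.mass,
                sigma=ff.sigma,
            )
        s = state.copy()
        force = np.zeros((topology.n_beads, 3))
        first_chunk = 0
        init_forces = True
    s.validate(topology)
    model = _MODEL_CODE[act.model]
    if model == _kernels.ABP and s.orientations is None:
        s.orientations = random_orientations(
            topology.n_beads, np.random.default_rng(params.seed)
        )
    ori = s.orientations if s.orientations is not None else np.zeros((1, 3))
    if model == _kernels.ABP and act.Dr * params.dt > 0.1:
        raise ValueError("Dr*dt > 0.1: rotational update too coarse")

    excl = topology.bonded_mask() if ff.wca_excludes_bonded else np.eye(
        topology.n_beads, dtype=bool
    )
    bonds = np.ascontiguousarray(topology.bonds)
    # kernel calls are capped at SUB_MAX steps so per-chunk noise buffers
    # stay small; one child seed per call
    SUB_MAX = 4000
    n_samples = -(-params.n_steps // params.sample_every)
    n_calls = first_chunk + params.n_steps // min(params.sample_every, SUB_MAX)
    n_calls += n_samples + 2
    seeds = _chunk_seeds(params.seed, max(n_calls, 1))

    times, rgs, og, opa, coms, kin = [], [], [], [], [], []
    frames = [] if store_frames else None

    def sample(step_index):
        times.append(s.time)
        rgs.append(
            radius_of_gyration(s.positions) if topology.n_beads > 1 else 0.0
        )
        try:
            g, per = order_parameter(s, topology, v_floor=act.v_floor)
        except ValueError:
            g, per = np.nan, np.full(topology.n_arms, np.nan)
        og.append(g)
        opa.append(per)
        coms.append(s.positions.mean(axis=0))
        kin.append(0.5 * params.mass * float(np.mean(np.sum(s.velocities**2, axis=1))))
        if store_frames:
            frames.append(s.copy())
        for obs in observers:
            obs(step_index, s)

    nb = topology.n_beads
    Dr = act.Dr if model == _kernels.ABP else 0.0
    steps_left = params.n_steps
    steps_done = 0
    chunk = first_chunk
    while steps_left > 0:
        interval = min(params.sample_every, steps_left)
        done_in_interval = 0
        while done_in_interval < interval:
            n_sub = min(SUB_MAX, interval - done_in_interval)
            crng = np.random.default_rng(seeds[chunk])
            noise = crng.standard_normal((n_sub + 1, nb, 3))
            rot = (
                crng.standard_normal((n_sub, nb, 3))
                if model == _kernels.ABP
                else np.zeros((0, nb, 3))
            )
            _kernels.advance(
                s.positions, s.velocities, ori, force, bonds, excl,
                ff.KB, ff.l0, ff.epsilon, ff.sigma**2, ff.cutoff**2,
                params.mass, params.gamma, act.kBT, params.dt,
                act.fa, model, Dr, act.v_floor,
                n_sub, noise, rot, init_forces,
            )
            init_forces = False
            chunk += 1
            done_in_interval += n_sub
        steps_left -= interval
        steps_done += interval
        s.time += interval * params.dt
        if not (np.isfinite(s.positions).all() and np.isfinite(s.velocities).all()):
            bad = np.nonzero(~np.isfinite(s.positions).all(axis=1))[0]
            bead = int(bad[0]) if len(bad) else int(
                np.nonzero(~np.isfinite(s.velocities).all(axis=1))[0][0]
            )
            finite_f = force[np.isfinite(force)]
            max_f = np.abs(finite_f).max() if finite_f.size else float("nan")
            raise FloatingPointError(
                f"non-finite state after step {steps_done} (bead {bead}, "
                f"max |F| = {max_f:.3g}); reduce dt"
            )
        sample(steps_done)
    if params.n_steps == 0:
        sample(0)

    traj = Trajectory(
        times=np.asarray(times),
        rg=np.asarray(rgs),
        order_global=np.asarray(og),
        order_per_arm=np.asarray(opa),
        com=np.asarray(coms),
        kinetic_per_bead=np.asarray(kin),
        final_state=s,
        frames=frames,
    )
    cp = Checkpoint(state=s.copy(), force=force.copy(), chunk_index=chunk,
                    steps_done=steps_done)
    return traj, cp


def continue_run(
    params: SimulationParams,
    topology: StarTopology,
    checkpoint: Checkpoint,
    extra_steps: int,
    **kwargs,
) -> tuple[Trajectory, Checkpoint]:
    """Continue from a checkpoint for ``extra_steps`` more steps."""
    p = replace(params, n_steps=extra_steps)
    return run(p, topology, restart=checkpoint, **kwargs)
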