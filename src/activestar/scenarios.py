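"""Packaged experiment presets and synthetic test fixtures.

Each registered scenario resolves, at reduction factor 1, to the study
conditions of one figure-level experiment (topology lists, activity model,
f_a/(kBT) grid, run length, timestep, replicate seeds).  Reduced variants
divide arm length and run length by the reduction factor and thin the
activity grid, leaving every physical constant untouched, so a desk-scale
sweep probes the same physics at smaller size.  Full-scale runs span up to
5e8 steps and are cluster work; they are supported but long-running.

:func:`synthetic_velocity_field` builds exactly ordered velocity fields on
straight-arm star conformations, which lets the whole analysis stack be
unit-tested without any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .activity import ActivityParams, kBT_for_ratio
from .forcefield import ForceFieldParams
from .integrator import SimulationParams, default_dt
from .topology import StarTopology, SystemState, build_star

__all__ = ["Scenario", "SCENARIOS", "make_scenario", "scenario_params",
           "synthetic_velocity_field"]


@dataclass(frozen=True)
class Scenario:
    """A fully resolved sweep definition."""

    name: str
    description: str
    model: str
    n_arms: tuple
    arm_length: int
    ratios: tuple
    replicates: int = 3
    n_steps: int = 500_000_000
    base_seed: int = 7000
    reduction: int = 1

    @property
    def seeds(self) -> tuple:
        return tuple(self.base_seed + r for r in range(self.replicates))

    def dt(self, ratio: float) -> float:
        return default_dt(ratio)


_FULL = dict(replicates=3, n_steps=500_000_000)

SCENARIOS = {
    "fig3a_scaling": Scenario(
        "fig3a_scaling",
        "Rg versus arm length for velocity-aligned n=3 stars, below and "
        "above the ordering transition",
        "velocity_aligned", (3,), 100, (20.0, 150.0, 200.0), **_FULL,
    ),
    "fig3b_rg_dist": Scenario(
        "fig3b_rg_dist",
        "Rg distributions of the velocity-aligned n=3, N=100 star across "
        "the transition (multimodal above it)",
        "velocity_aligned", (3,), 100, (50.0, 100.0, 110.0, 120.0, 143.0, 200.0, 300.0),
        **_FULL,
    ),
    "fig3c_swelling": Scenario(
        "fig3c_swelling",
        "Swelling ratio versus activity for velocity-aligned stars, N=100; "
        "steep rise between ~100 and ~120",
        "velocity_aligned", (2, 3, 4, 5), 100,
        (0.0, 25.0, 50.0, 75.0, 90.0, 100.0, 110.0, 120.0, 150.0, 200.0, 250.0, 300.0),
        **_FULL,
    ),
    "fig3d_gn": Scenario(
        "fig3d_gn",
        "Shape factor g(n) of velocity-aligned N=100 stars in the disordered "
        "(slope ~ -0.6) and ordered (~ -1.5) regimes",
        "velocity_aligned", (2, 3, 4, 5, 6), 100, (20.0, 200.0), **_FULL,
    ),
    "fig4a_scaling": Scenario(
        "fig4a_scaling",
        "Rg versus arm length for ABP n=3 stars (scaling ~0.6 at all activities)",
        "abp", (3,), 100, (10.0, 50.0, 150.0, 300.0), **_FULL,
    ),
    "fig4b_rg_dist": Scenario(
        "fig4b_rg_dist",
        "Rg distributions of the ABP n=3, N=100 star (unimodal, gradual shift)",
        "abp", (3,), 100, (10.0, 50.0, 100.0, 150.0, 300.0), **_FULL,
    ),
    "fig4c_swelling": Scenario(
        "fig4c_swelling",
        "Swelling ratio versus activity for ABP stars, N=100 (gradual growth)",
        "abp", (2, 3, 4, 5), 100,
        (0.0, 10.0, 25.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0), **_FULL,
    ),
    "fig4d_gn": Scenario(
        "fig4d_gn",
        "Shape factor g(n) of ABP N=50 stars (slope between -0.35 and -0.5)",
        "abp", (2, 3, 4, 5, 6), 50, (10.0, 150.0, 300.0), **_FULL,
    ),
    "fig5_order": Scenario(
        "fig5_order",
        "Velocity-bond order parameter of velocity-aligned stars, N=100, "
        "fa/(kBT)=200: n+1 collective states",
        "velocity_aligned", (2, 3, 4, 5), 100, (200.0,), **_FULL,
    ),
}


def make_scenario(name: str, reduction: int = 1) -> Scenario:
    """Return a registered scenario, optionally at reduced scale.

    Reduction r divides the arm length and the run length by r (clamped to
    at least 5 beads / 10^5 steps) and keeps every other ratio of the
    activity grid for r >= 4; seeds and physical constants are unchanged.
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; registered: {sorted(SCENARIOS)}"
        )
    if reduction < 1:
        raise ValueError("reduction must be >= 1")
    sc = SCENARIOS[name]
    if reduction == 1:
        return sc
    ratios = sc.ratios[::2] if reduction >= 4 and len(sc.ratios) > 3 else sc.ratios
    return replace(
        sc,
        arm_length=max(5, sc.arm_length // reduction),
        n_steps=max(100_000, sc.n_steps // reduction),
        ratios=ratios,
        reduction=reduction,
    )


def scenario_params(
    sc: Scenario, n_arms: int, ratio: float, seed: int, sample_every: int = 1000
) -> tuple[StarTopology, SimulationParams]:
    """Materialise one cell of a scenario sweep as runnable parameters."""
    if ratio == 0.0:
        act = ActivityParams(model="passive", fa=0.0, kBT=1.0)
    else:
        act = ActivityParams(model=sc.model, fa=1.0, kBT=kBT_for_ratio(ratio))
    params = SimulationParams(
        activity=act,
        forcefield=ForceFieldParams(),
        dt=sc.dt(ratio),
        n_steps=sc.n_steps,
        sample_every=sample_every,
        seed=seed,
    )
    return build_star(n_arms, sc.arm_length), params


_ARM_DIRECTIONS = np.array(
    [
        [1.0, 0.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.0, -1.0],
    ]
)


def synthetic_velocity_field(
    topology: StarTopology,
    mode: str,
    seed: int = 0,
    k: int | None = None,
    speed: float = 1.0,
) -> SystemState:
    """Straight-arm star conformation with an exactly ordered velocity field.

    Arms radiate along coordinate axes (so up to 6 arms).  Modes:

    * ``"parallel"``: every arm bead moves along its arm axis (order 1).
    * ``"perpendicular"``: every arm bead moves at right angles to its arm
      (order 0).
    * ``"isotropic"``: random directions (order ~ 1/2 in expectation).
    * ``"mixed"``: arms ``0..k-1`` parallel, the rest perpendicular.

    The centre bead is left at rest (excluded from the order average) except
    in isotropic mode.
    """
    if topology.n_arms > 6:
        raise ValueError("synthetic field supports at most 6 arms")
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    perp = {0: np.array([0.0, 1.0, 0.0]), 1: np.array([0.0, 0.0, 1.0]),
            2: np.array([1.0, 0.0, 0.0])}
    if mode == "mixed" and k is None:
        raise ValueError("mixed mode needs k (number of parallel arms)")
    for a in range(topology.n_arms):
        d = _ARM_DIRECTIONS[a]
        sl = topology.arm_slice(a)
        for off, i in enumerate(range(sl.start, sl.stop)):
            pos[i] = (off + 1) * d
        if mode == "parallel" or (mode == "mixed" and a < k):
            vel[sl] = speed * d
        elif mode in ("perpendicular", "mixed"):
            vel[sl] = speed * perp[np.argmax(np.abs(d))]
        elif mode == "isotropic":
            v = rng.normal(size=(sl.stop - sl.start, 3))
            vel[sl] = speed * v / np.linalg.norm(v, axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if mode == "isotropic":
        v = rng.normal(size=3)
        vel[topology.center_index] = speed * v / np.linalg.norm(v)
    return SystemState(positions=pos, velocities=vel, time=0.0)
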