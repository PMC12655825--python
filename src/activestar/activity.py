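"""The two monomer-activity models: uncorrelated ABP and velocity-aligned.

Active Brownian particle (ABP) beads carry an intrinsic propulsion director
n_i; the active force is f_a n_i and the director diffuses on the unit sphere
with rotational diffusion coefficient D_r = 3 D / l0^2, D = kBT / gamma (so
the persistence of propulsion is tied to the translational diffusivity of
the bath).  Velocity-aligned beads are pushed along their own instantaneous
velocity, f_a v_i / |v_i|, which correlates activity between interacting
neighbours because collisions and bonds reshape v_i directly.

Activity strength is reported as the ratio f_a/(kBT).  Following the study
conditions this package emulates, f_a is held at 1 and kBT is varied from
1 (passive-like) down to 0.0033, spanning f_a/(kBT) from ~1 to 300; the
strictly passive reference uses f_a = 0, kBT = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivityParams",
    "kBT_for_ratio",
    "abp_update_orientations",
    "abp_active_forces",
    "va_active_forces",
    "random_orientations",
]

MODELS = ("passive", "abp", "velocity_aligned")


@dataclass(frozen=True)
class ActivityParams:
    """Activity model selection and constants.

    model : one of ``"passive"``, ``"abp"``, ``"velocity_aligned"``.
    fa : active force amplitude (0 for passive).
    kBT : thermal energy of the implicit solvent.
    l0 : bond length entering D_r = 3 D / l0^2 for the ABP director.
    gamma : translational friction, needed for D = kBT / gamma.
    v_floor : speed below which the velocity-aligned force is zeroed
        (the alignment direction is undefined at v = 0).
    """

    model: str = "passive"
    fa: float = 0.0
    kBT: float = 1.0
    l0: float = 1.0
    gamma: float = 1.0
    v_floor: float = 1e-12

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown activity model {self.model!r}; choose from {MODELS}")
        if self.fa < 0:
            raise ValueError("fa must be >= 0")
        if self.kBT <= 0:
            raise ValueError("kBT must be > 0 (use model='passive', fa=0 for no activity)")
        if self.model == "passive" and self.fa != 0:
            raise ValueError("passive model requires fa = 0")

    @property
    def ratio(self) -> float:
        """Activity-to-temperature ratio f_a/(kBT)."""
        return self.fa / self.kBT

    @property
    def D(self) -> float:
        """Translational diffusion coefficient kBT/gamma."""
        return self.kBT / self.gamma

    @property
    def Dr(self) -> float:
        """Rotational diffusion coefficient of the ABP director, 3 D / l0^2."""
        return 3.0 * self.D / self.l0**2

    @property
    def gamma_r(self) -> float:
        """Rotational friction kBT / D_r."""
        return self.kBT / self.Dr


def kBT_for_ratio(ratio: float, fa: float = 1.0) -> float:
    """Temperature realising a requested f_a/(kBT) at fixed f_a (default 1)."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0; use the passive model for ratio 0")
    return fa / ratio


def random_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n isotropic unit vectors."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def abp_update_orientations(
    orientations: np.ndarray, dt: float, Dr: float, rng: np.random.Generator
) -> np.ndarray:
    """One Euler-Maruyama step of rotational diffusion on the unit sphere.

    Each director is kicked by sqrt(2 Dr dt) * (xi x n) with xi standard
    Gaussian, giving angular variance 2 Dr dt per axis perpendicular to n,
    then renormalized.  The resulting autocorrelation is
    <n(0) . n(t)> = exp(-2 Dr t).
    """
    if Dr * dt > 0.1:
        raise ValueError(
            f"Dr*dt = {Dr * dt:.3g} > 0.1: rotational step too coarse for "
            "Euler-Maruyama on the sphere"
        )
    if Dr == 0.0:
        return orientations.copy()
    xi = rng.normal(size=orientations.shape)
    n = orientations + np.sqrt(2.0 * Dr * dt) * np.cross(xi, orientations)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def abp_active_forces(orientations: np.ndarray, fa: float) -> np.ndarray:
    """Active force f_a n_i on each bead."""
    return fa * orientations


def va_active_forces(
    velocities: np.ndarray, fa: float, v_floor: float = 1e-12
) -> np.ndarray:
    """Velocity-aligned active force f_a v_i/|v_i|; zero below ``v_floor``."""
    speed = np.linalg.norm(velocities, axis=1)
    out = np.zeros_like(velocities)
    ok = speed >= v_floor
    out[ok] = fa * velocities[ok] / speed[ok, None]
    return out
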