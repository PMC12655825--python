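"""Conservative interactions: harmonic bonds and WCA excluded volume.

The bond potential is the standard harmonic well U_b = 1/2 K_B (l - l0)^2.
Excluded volume uses the Weeks-Chandler-Andersen potential: Lennard-Jones
truncated at r_c = 2^(1/6) sigma and shifted up by epsilon so that energy and
force vanish continuously at the cutoff, leaving a purely repulsive core.
By default WCA acts on every pair except directly bonded neighbours (whose
separation is pinned near sigma by the stiff bond anyway); set
``wca_excludes_bonded=False`` to evaluate it on all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ForceFieldParams", "bond_energy_forces", "wca_energy_forces"]

WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants in reduced units.

    KB : harmonic bond spring constant (energy/length^2), default 1e4.
    l0 : equilibrium bond length, default 1.
    epsilon, sigma : WCA energy and length scales, default 1.
    wca_excludes_bonded : whether 1-2 pairs skip the WCA term.

    The WCA cutoff is tied to sigma (2^(1/6) sigma) and not independently
    settable.
    """

    KB: float = 1.0e4
    l0: float = 1.0
    epsilon: float = 1.0
    sigma: float = 1.0
    wca_excludes_bonded: bool = True

    def __post_init__(self):
        for name in ("KB", "l0", "epsilon", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def cutoff(self) -> float:
        return WCA_CUTOFF_FACTOR * self.sigma


def bond_energy_forces(state, topology, ff: ForceFieldParams):
    """Total harmonic-bond energy and per-bead forces.

    Energy = sum over bonds of 1/2 KB (l - l0)^2; forces are the exact
    negative gradient, equal and opposite on the two bonded beads.
    """
    pos = state.positions
    i, j = topology.bonds[:, 0], topology.bonds[:, 1]
    d = pos[j] - pos[i]
    l = np.linalg.norm(d, axis=1)
    if np.any(l < 1e-12):
        b = int(np.argmin(l))
        raise ValueError(
            f"bond {b} ({i[b]}-{j[b]}) has zero length; force direction undefined"
        )
    dl = l - ff.l0
    energy = 0.5 * ff.KB * np.sum(dl**2)
    # force on j: -KB (l - l0) * unit(j - i)
    fpair = (-ff.KB * dl / l)[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, j, fpair)
    np.add.at(forces, i, -fpair)
    return float(energy), forces


def wca_energy_forces(state, ff: ForceFieldParams, topology=None):
    """Total WCA energy and per-bead forces over all interacting pairs.

    Pair energy for r < 2^(1/6) sigma is 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps,
    zero beyond.  If ``topology`` is given and ``ff.wca_excludes_bonded`` is
    true, directly bonded pairs are skipped.
    """
    pos = state.positions
    n = len(pos)
    diff = pos[:, None, :] - pos[None, :, :]
    r2 = np.sum(diff**2, axis=-1)
    iu = np.triu_indices(n, k=1)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = True
    if topology is not None and ff.wca_excludes_bonded:
        mask[topology.bonds[:, 0], topology.bonds[:, 1]] = False
        mask[topology.bonds[:, 1], topology.bonds[:, 0]] = False
    cut2 = ff.cutoff**2
    act = mask & (r2 < cut2)
    if np.any(act & (r2 < (1e-6 * ff.sigma) ** 2)):
        ii, jj = np.nonzero(act & (r2 < (1e-6 * ff.sigma) ** 2))
        raise ValueError(
            f"pair ({ii[0]}, {jj[0]}) closer than 1e-6 sigma; WCA would overflow"
        )
    ii, jj = np.nonzero(act)
    rr2 = r2[ii, jj]
    s2 = ff.sigma**2 / rr2
    s6 = s2**3
    energy = float(np.sum(4.0 * ff.epsilon * (s6**2 - s6) + ff.epsilon))
    # |F| = 24 eps (2 (sigma/r)^12 - (sigma/r)^6) / r, along the separation
    fmag_over_r = 24.0 * ff.epsilon * (2.0 * s6**2 - s6) / rr2
    fpair = fmag_over_r[:, None] * diff[ii, jj]
    forces = np.zeros_like(pos)
    np.add.at(forces, ii, fpair)
    np.add.at(forces, jj, -fpair)
    return energy, forces
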