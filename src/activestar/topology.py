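"""Star and linear bead-spring topologies and initial conformations.

A star polymer here is ``n_arms`` linear arms of ``arm_length`` beads each,
all bonded to a single central monomer.  Two arms degenerate into a linear
chain.  Bead 0 is always the center; arm ``k`` occupies the contiguous index
block ``[1 + k*N, 1 + (k+1)*N)`` with the bead bonded to the center first,
so per-arm observables are plain slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StarTopology",
    "SystemState",
    "build_star",
    "build_chain",
    "initial_conformation",
    "to_lammps_data",
]


@dataclass(frozen=True)
class StarTopology:
    """Connectivity of a star (or path) bead-spring molecule.

    Attributes
    ----------
    n_arms : int
        Number of arms attached to the central monomer.
    arm_lengths : tuple of int
        Beads per arm.  Equal for stars built with :func:`build_star`;
        :func:`build_chain` may produce two arms differing by one bead.
    bonds : (n_bonds, 2) int array
        Bead-index pairs, each listed once.
    center_index : int
        Index of the central monomer (always 0).
    arm_of_bead : (n_beads,) int array
        Arm id per bead; the center carries -1.
    """

    n_arms: int
    arm_lengths: tuple
    bonds: np.ndarray = field(repr=False)
    center_index: int = 0
    arm_of_bead: np.ndarray = field(default=None, repr=False)

    @property
    def n_beads(self) -> int:
        return int(sum(self.arm_lengths)) + 1

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def arm_length(self) -> int:
        """Common arm length; raises if the arms are unequal."""
        if len(set(self.arm_lengths)) != 1:
            raise ValueError("arms have unequal lengths")
        return self.arm_lengths[0]

    def arm_slice(self, k: int) -> slice:
        start = 1 + sum(self.arm_lengths[:k])
        return slice(start, start + self.arm_lengths[k])

    def neighbor_lists(self):
        """Per-bead lists of bonded neighbours."""
        nbrs = [[] for _ in range(self.n_beads)]
        for i, j in self.bonds:
            nbrs[int(i)].append(int(j))
            nbrs[int(j)].append(int(i))
        return nbrs

    def bonded_mask(self) -> np.ndarray:
        """(n, n) boolean matrix marking bonded pairs and the diagonal."""
        m = np.zeros((self.n_beads, self.n_beads), dtype=bool)
        np.fill_diagonal(m, True)
        m[self.bonds[:, 0], self.bonds[:, 1]] = True
        m[self.bonds[:, 1], self.bonds[:, 0]] = True
        return m


@dataclass
class SystemState:
    """Instantaneous mechanical state of the molecule.

    ``orientations`` holds the self-propulsion directors of the ABP model
    (unit vectors, one per bead); it is ``None`` for the passive and
    velocity-aligned models.  All quantities are in reduced (dimensionless)
    Lennard-Jones-style units.
    """

    positions: np.ndarray
    velocities: np.ndarray
    orientations: np.ndarray | None = None
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            None if self.orientations is None else self.orientations.copy(),
            self.time,
        )

    def validate(self, topology: StarTopology) -> None:
        n = topology.n_beads
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError(
                f"state arrays must be ({n}, 3); got positions "
                f"{self.positions.shape}, velocities {self.velocities.shape}"
            )
        if self.orientations is not None:
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("ABP orientations must be unit vectors")


def _assemble(arm_lengths) -> StarTopology:
    bonds = []
    arm_of_bead = [-1]
    idx = 1
    for k, N in enumerate(arm_lengths):
        prev = 0
        for _ in range(N):
            bonds.append((prev, idx))
            arm_of_bead.append(k)
            prev = idx
            idx += 1
    return StarTopology(
        n_arms=len(arm_lengths),
        arm_lengths=tuple(int(N) for N in arm_lengths),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        center_index=0,
        arm_of_bead=np.asarray(arm_of_bead, dtype=np.int64),
    )


def build_star(n_arms: int, arm_length: int) -> StarTopology:
    """Build an ``n_arms``-arm star of ``arm_length`` beads per arm.

    Total beads = ``n_arms * arm_length + 1``; the bond graph is a tree with
    the center of degree ``n_arms``.  ``n_arms=2`` yields a path graph
    (linear chain).
    """
    if n_arms < 2:
        raise ValueError(f"n_arms must be >= 2 (got {n_arms}); a star needs at least two arms")
    if arm_length < 1:
        raise ValueError(f"arm_length must be >= 1 (got {arm_length})")
    return _assemble([arm_length] * n_arms)


def build_chain(n_beads: int) -> StarTopology:
    """Build a linear chain of ``n_beads`` as a two-arm topology.

    The "center" sits mid-chain; for even ``n_beads`` the two arms differ
    by one bead.  Used e.g. as the equal-monomer-count reference when
    computing the star shape factor g(n).
    """
    if n_beads < 2:
        raise ValueError(f"n_beads must be >= 2 (got {n_beads})")
    rest = n_beads - 1
    return _assemble([rest - rest // 2, rest // 2])


def initial_conformation(
    topology: StarTopology,
    bond_length: float = 1.0,
    seed: int = 0,
    kBT: float = 1.0,
    mass: float = 1.0,
    sigma: float = 1.0,
    min_separation: float = 0.8,
    max_sweeps: int = 2000,
) -> SystemState:
    """Generate a random non-overlapping conformation with thermal velocities.

    Arms grow from the center as random walks that reject placements closer
    than ``min_separation * sigma`` to any existing bead; a capped-force
    soft-core push-off then removes residual clashes while a stiff harmonic
    term keeps every bond at ``bond_length`` (within 1e-6 after the final
    bond projection).  Velocities are Maxwell-Boltzmann at ``kBT``.
    Deterministic for a given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    pos = np.zeros((n, 3))
    min_d = min_separation * sigma

    # random self-avoiding growth, arm by arm
    for k in range(topology.n_arms):
        sl = topology.arm_slice(k)
        prev = topology.center_index
        for i in range(sl.start, sl.stop):
            for attempt in range(200):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = pos[prev] + bond_length * u
                d = np.linalg.norm(pos[:i] - cand, axis=1)
                d[prev] = np.inf  # bonded neighbour is at bond_length by construction
                if np.all(d >= min_d):
                    break
            else:
                raise RuntimeError(
                    f"could not place bead {i} (arm {k}) without a clash "
                    f"after 200 attempts"
                )
            pos[i] = cand
            prev = i

    pos = _pushoff_relax(pos, topology, bond_length, min_d, max_sweeps)

    vel = rng.normal(scale=np.sqrt(kBT / mass), size=(n, 3))
    return SystemState(positions=pos, velocities=vel, time=0.0)


def _pushoff_relax(pos, topology, bond_length, min_d, max_sweeps):
    """Capped-force steepest-descent push-off + exact bond re-projection."""
    bonds = topology.bonds
    bm = topology.bonded_mask()
    n = len(pos)
    for sweep in range(max_sweeps):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        close = (~bm) & (dist < min_d)
        if not close.any():
            break
        # soft push along the separation vector, displacement capped at 0.05
        with np.errstate(divide="ignore", invalid="ignore"):
            push = np.where(close[:, :, None], diff / np.maximum(dist, 1e-9)[:, :, None], 0.0)
        pos = pos + 0.05 * push.sum(axis=1)
        # restore exact bond lengths walking out from the center
        for i, j in bonds:
            b = pos[j] - pos[i]
            pos[j] = pos[i] + b * (bond_length / np.linalg.norm(b))
    else:
        i, j = np.unravel_index(np.argmin(dist + np.where(bm, np.inf, 0.0)), dist.shape)
        raise RuntimeError(
            f"push-off failed to separate beads {i} and {j} "
            f"(distance {dist[i, j]:.3f} < {min_d:.3f}) after {max_sweeps} sweeps"
        )
    return pos


def to_lammps_data(topology: StarTopology, state: SystemState) -> str:
    """Serialize topology + coordinates as a LAMMPS data file (atoms + bonds)."""
    n = topology.n_beads
    pos = state.positions
    lo, hi = pos.min() - 5.0, pos.max() + 5.0
    lines = [
        "LAMMPS data file: bead-spring star polymer",
        "",
        f"{n} atoms",
        f"{topology.n_bonds} bonds",
        "",
        "1 atom types",
        "1 bond types",
        "",
        f"{lo:.6f} {hi:.6f} xlo xhi",
        f"{lo:.6f} {hi:.6f} ylo yhi",
        f"{lo:.6f} {hi:.6f} zlo zhi",
        "",
        "Atoms # bond",
        "",
    ]
    for i in range(n):
        x, y, z = pos[i]
        lines.append(f"{i + 1} 1 1 {x:.8f} {y:.8f} {z:.8f}")
    lines += ["", "Bonds", ""]
    for b, (i, j) in enumerate(topology.bonds):
        lines.append(f"{b + 1} 1 {i + 1} {j + 1}")
    return "\n".join(lines) + "\n"
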