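"""Compiled inner loops for the Langevin integrator.

Everything here is a plain-array mirror of the physics defined in
:mod:`activestar.forcefield` and :mod:`activestar.activity`; the numpy
implementations there are the readable reference, these numba kernels are
what :func:`activestar.integrator.run` actually executes.  A test pins the
two force routes together to 1e-12.

The RNG is numba's internal legacy stream, seeded once per kernel call; the
caller derives one child seed per chunk of steps from the run seed, which
makes whole runs reproducible and restartable at chunk boundaries.
"""

import numpy as np
from numba import njit

# activity model codes shared with the integrator
PASSIVE, ABP, VELOCITY_ALIGNED = 0, 1, 2


@njit(cache=True, fastmath=True, error_model="numpy")
def conservative_forces(pos, bonds, excl, KB, l0, eps, sig2, cut2, F):
    """Harmonic-bond + WCA forces into F (overwritten); returns total energy."""
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    energy = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = l - l0
        energy += 0.5 * KB * dl * dl
        fac = -KB * dl / l
        F[j, 0] += fac * dx
        F[j, 1] += fac * dy
        F[j, 2] += fac * dz
        F[i, 0] -= fac * dx
        F[i, 1] -= fac * dy
        F[i, 2] -= fac * dz
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2:
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                energy += 4.0 * eps * (s6 * s6 - s6) + eps
                fac = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                F[i, 0] += fac * dx
                F[i, 1] += fac * dy
                F[i, 2] += fac * dz
                F[j, 0] -= fac * dx
                F[j, 1] -= fac * dy
                F[j, 2] -= fac * dz
    return energy


@njit(cache=True, fastmath=True, error_model="numpy")
def build_pair_list(pos, excl, rlist2, pairs):
    """Collect non-excluded pairs within sqrt(rlist2); returns the count."""
    n = pos.shape[0]
    cnt = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < rlist2:
                pairs[cnt, 0] = i
                pairs[cnt, 1] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True, error_model="numpy")
def conservative_forces_nlist(pos, bonds, pairs, n_pairs, KB, l0, eps,
                              sig2, cut2, F):
    """Same physics as :func:`conservative_forces`, WCA over a pair list."""
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    energy = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = l - l0
        energy += 0.5 * KB * dl * dl
        fac = -KB * dl / l
        F[j, 0] += fac * dx
        F[j, 1] += fac * dy
        F[j, 2] += fac * dz
        F[i, 0] -= fac * dx
        F[i, 1] -= fac * dy
        F[i, 2] -= fac * dz
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < cut2:
            s2 = sig2 / r2
            s6 = s2 * s2 * s2
            energy += 4.0 * eps * (s6 * s6 - s6) + eps
            fac = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            F[i, 0] += fac * dx
            F[i, 1] += fac * dy
            F[i, 2] += fac * dz
            F[j, 0] -= fac * dx
            F[j, 1] -= fac * dy
            F[j, 2] -= fac * dz
    return energy


@njit(cache=True, fastmath=True, error_model="numpy")
def _add_noncons(pos, vel, ori, F, bonds, excl, KB, l0, eps, sig2, cut2,
                 gamma, kBT, dt, fa, model, v_floor, rand_scale):
    """Conservative + active + friction + fresh random force, into F."""
    n = pos.shape[0]
    conservative_forces(pos, bonds, excl, KB, l0, eps, sig2, cut2, F)
    if model == ABP and fa != 0.0:
        for i in range(n):
            F[i, 0] += fa * ori[i, 0]
            F[i, 1] += fa * ori[i, 1]
            F[i, 2] += fa * ori[i, 2]
    elif model == VELOCITY_ALIGNED and fa != 0.0:
        for i in range(n):
            sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            if sp >= v_floor:
                F[i, 0] += fa * vel[i, 0] / sp
                F[i, 1] += fa * vel[i, 1] / sp
                F[i, 2] += fa * vel[i, 2] / sp
    xi = np.random.standard_normal((n, 3))
    for i in range(n):
        F[i, 0] += -gamma * vel[i, 0] + rand_scale * xi[i, 0]
        F[i, 1] += -gamma * vel[i, 1] + rand_scale * xi[i, 1]
        F[i, 2] += -gamma * vel[i, 2] + rand_scale * xi[i, 2]


@njit(cache=True, fastmath=True, error_model="numpy")
def _add_noncons_nlist(pos, vel, ori, F, bonds, pairs, n_pairs, KB, l0, eps,
                       sig2, cut2, gamma, kBT, dt, fa, model, v_floor,
                       rand_scale, xi):
    """Pair-list variant of :func:`_add_noncons` (identical physics); the
    Gaussian draw ``xi`` for this evaluation is supplied by the caller."""
    n = pos.shape[0]
    conservative_forces_nlist(pos, bonds, pairs, n_pairs, KB, l0, eps,
                              sig2, cut2, F)
    if model == ABP and fa != 0.0:
        for i in range(n):
            F[i, 0] += fa * ori[i, 0]
            F[i, 1] += fa * ori[i, 1]
            F[i, 2] += fa * ori[i, 2]
    elif model == VELOCITY_ALIGNED and fa != 0.0:
        for i in range(n):
            sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            if sp >= v_floor:
                F[i, 0] += fa * vel[i, 0] / sp
                F[i, 1] += fa * vel[i, 1] / sp
                F[i, 2] += fa * vel[i, 2] / sp
    for i in range(n):
        F[i, 0] += -gamma * vel[i, 0] + rand_scale * xi[i, 0]
        F[i, 1] += -gamma * vel[i, 1] + rand_scale * xi[i, 1]
        F[i, 2] += -gamma * vel[i, 2] + rand_scale * xi[i, 2]


@njit(cache=True, fastmath=True, error_model="numpy")
def advance(pos, vel, ori, F, bonds, excl, KB, l0, eps, sig2, cut2,
            mass, gamma, kBT, dt, fa, model, Dr, v_floor,
            n_steps, thermal_noise, rot_noise, init_forces):
    """Advance ``n_steps`` velocity-Verlet Langevin steps in place.

    Force layout follows the one-evaluation-per-step convention: the stored
    total force F closes step s and opens step s+1.  Friction and the
    velocity-aligned active force use the half-kicked post-drift velocity.
    ABP directors take one rotational Euler-Maruyama step per timestep.

    ``thermal_noise`` has shape (n_steps + 1, n, 3): row t + 1 feeds the
    force evaluation of step t, row 0 the initial evaluation when
    ``init_forces`` is set.  ``rot_noise`` is (n_steps, n, 3) for the ABP
    director updates (a dummy (0, n, 3) array otherwise).

    WCA pairs come from a Verlet list with skin 0.35 sigma, rebuilt whenever
    any bead has moved more than half the skin since the last build, which
    reproduces the all-pairs forces exactly (a test pins the two routes).
    """
    n = pos.shape[0]
    rand_scale = np.sqrt(2.0 * kBT * gamma / dt) if kBT > 0.0 else 0.0
    rot_scale = np.sqrt(2.0 * Dr * dt)
    half = 0.5 * dt / mass
    skin = 0.35 * np.sqrt(sig2)
    rlist2 = (np.sqrt(cut2) + skin) ** 2
    trigger2 = (0.5 * skin) ** 2
    pairs = np.empty((n * (n - 1) // 2, 2), dtype=np.int64)
    ref = pos.copy()
    n_pairs = build_pair_list(pos, excl, rlist2, pairs)
    if init_forces:
        _add_noncons_nlist(pos, vel, ori, F, bonds, pairs, n_pairs, KB, l0,
                           eps, sig2, cut2, gamma, kBT, dt, fa, model,
                           v_floor, rand_scale, thermal_noise[0])
    for t in range(n_steps):
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        if model == ABP and Dr > 0.0:
            xi = rot_noise[t]
            for i in range(n):
                cx = xi[i, 1] * ori[i, 2] - xi[i, 2] * ori[i, 1]
                cy = xi[i, 2] * ori[i, 0] - xi[i, 0] * ori[i, 2]
                cz = xi[i, 0] * ori[i, 1] - xi[i, 1] * ori[i, 0]
                nx = ori[i, 0] + rot_scale * cx
                ny = ori[i, 1] + rot_scale * cy
                nz = ori[i, 2] + rot_scale * cz
                inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
                ori[i, 0] = nx * inv
                ori[i, 1] = ny * inv
                ori[i, 2] = nz * inv
        moved = False
        for i in range(n):
            ddx = pos[i, 0] - ref[i, 0]
            ddy = pos[i, 1] - ref[i, 1]
            ddz = pos[i, 2] - ref[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > trigger2:
                moved = True
                break
        if moved:
            n_pairs = build_pair_list(pos, excl, rlist2, pairs)
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        _add_noncons_nlist(pos, vel, ori, F, bonds, pairs, n_pairs, KB, l0,
                           eps, sig2, cut2, gamma, kBT, dt, fa, model,
                           v_floor, rand_scale, thermal_noise[t + 1])
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
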