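"""Structural and dynamical observables for active star polymers.

Covers the gyration radius and its distribution, the star shape factor
g(n), power-law scaling fits, the velocity-bond order parameter and the
discrete arm-state machinery built on it, and the centre-of-mass MSD.

The order parameter of a snapshot is the bead average of |cos(alpha)|,
where alpha is the angle between a bead's velocity and each of its incident
bond vectors (averaged over the incident bonds first).  Isotropic
velocities give 1/2 (the mean of |cos| on the sphere); coherent motion
along the chain gives 1 and motion perpendicular to it gives 0.  Each arm
of a star picks the parallel or perpendicular branch quasi-independently,
so the number of parallel arms k in {0..n} labels the n+1 collective
states a velocity-aligned star can occupy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d

from .topology import StarTopology, SystemState

__all__ = [
    "OrderProfile",
    "radius_of_gyration",
    "g_factor",
    "fit_scaling_exponent",
    "order_parameter",
    "classify_arm_states",
    "count_states",
    "rg_histogram",
    "count_modes",
    "com_msd",
    "swelling_ratio",
    "time_average",
]

ARM_PERPENDICULAR, ARM_UNDECIDED, ARM_PARALLEL = -1, 0, 1


@dataclass
class OrderProfile:
    """Discrete arm-state series derived from per-arm order parameters.

    arm_states : (n_frames, n_arms) int array with -1 = perpendicular,
        0 = undecided, +1 = parallel.
    k_parallel : per-frame count of parallel arms, in {0..n_arms}.
    """

    arm_states: np.ndarray
    k_parallel: np.ndarray


def radius_of_gyration(positions: np.ndarray) -> float:
    """Root-mean-square distance of beads from their centre of mass."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        raise ValueError("radius of gyration needs at least 2 beads")
    com = positions.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((positions - com) ** 2, axis=1))))


def g_factor(rg2_star: float, rg2_linear: float) -> float:
    """Shape factor g(n) = Rg^2(star) / Rg^2(linear chain, same bead count)."""
    if rg2_star <= 0 or rg2_linear <= 0:
        raise ValueError("squared gyration radii must be positive")
    return rg2_star / rg2_linear


def fit_scaling_exponent(sizes, rg_means):
    """Least-squares slope of log Rg versus log size.

    ``sizes`` is the total bead count of each molecule; the returned slope
    is the scaling exponent nu in Rg ~ size^nu (~3/5 for a self-avoiding
    chain in good solvent, 1 for a rod).  Returns (slope, stderr).
    """
    sizes = np.asarray(sizes, dtype=float)
    rg_means = np.asarray(rg_means, dtype=float)
    if len(sizes) < 3:
        raise ValueError("need at least 3 size points to fit a scaling exponent")
    if np.any(sizes <= 0) or np.any(rg_means <= 0):
        raise ValueError("sizes and Rg values must be positive")
    if np.allclose(sizes, sizes[0]):
        raise ValueError("all sizes equal; scaling fit is degenerate")
    res = stats.linregress(np.log(sizes), np.log(rg_means))
    return float(res.slope), float(res.stderr)


def order_parameter(
    state: SystemState, topology: StarTopology, v_floor: float = 1e-12
):
    """Velocity-bond order parameter of one snapshot.

    For every bead faster than ``v_floor``: mean over its incident bonds of
    |cos| of the angle between velocity and bond.  Returns the global bead
    average and the per-arm averages (centre bead contributes only to the
    global value).  Raises if every bead is below ``v_floor``.
    """
    vel = state.velocities
    pos = state.positions
    if topology.n_bonds == 0:
        raise ValueError("order parameter undefined: topology has no bonds")
    speeds = np.linalg.norm(vel, axis=1)
    ok = speeds >= v_floor
    if not ok.any():
        raise ValueError("order parameter undefined: all speeds below v_floor")
    bi, bj = topology.bonds[:, 0], topology.bonds[:, 1]
    bvec = pos[bj] - pos[bi]
    bnorm = np.linalg.norm(bvec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_i = np.abs(np.sum(bvec * vel[bi], axis=1)) / (bnorm * speeds[bi])
        cos_j = np.abs(np.sum(bvec * vel[bj], axis=1)) / (bnorm * speeds[bj])
    acc = np.zeros(topology.n_beads)
    cnt = np.zeros(topology.n_beads)
    np.add.at(acc, bi[ok[bi]], cos_i[ok[bi]])
    np.add.at(cnt, bi[ok[bi]], 1.0)
    np.add.at(acc, bj[ok[bj]], cos_j[ok[bj]])
    np.add.at(cnt, bj[ok[bj]], 1.0)
    per_bead = np.full(topology.n_beads, np.nan)
    np.divide(acc, cnt, out=per_bead, where=cnt > 0)
    global_val = float(np.nanmean(per_bead))
    per_arm = np.empty(topology.n_arms)
    for k in range(topology.n_arms):
        vals = per_bead[topology.arm_slice(k)]
        per_arm[k] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
    return global_val, per_arm


def classify_arm_states(
    order_per_arm: np.ndarray,
    thresholds: tuple = (0.25, 0.75),
    smooth_window: int = 25,
) -> OrderProfile:
    """Label each arm per frame as perpendicular / undecided / parallel.

    The per-arm order series is smoothed with a centred moving average of
    ``smooth_window`` frames, then thresholded: below ``t_low`` the arm is
    perpendicular to its own motion, above ``t_high`` it moves along its
    contour (parallel).  ``k_parallel`` counts parallel arms per frame; as
    the arms are exchangeable it indexes the n+1 collective states.
    """
    t_low, t_high = thresholds
    if not (0.0 < t_low < t_high < 1.0):
        raise ValueError("thresholds must satisfy 0 < t_low < t_high < 1")
    series = np.asarray(order_per_arm, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if smooth_window > 1 and len(series) >= smooth_window:
        kern = np.ones(smooth_window)
        norm = np.convolve(np.ones(len(series)), kern, mode="same")
        series = np.apply_along_axis(
            lambda s: np.convolve(s, kern, mode="same") / norm, 0, series
        )
    states = np.zeros(series.shape, dtype=int)
    states[series < t_low] = ARM_PERPENDICULAR
    states[series > t_high] = ARM_PARALLEL
    return OrderProfile(arm_states=states, k_parallel=(states == ARM_PARALLEL).sum(axis=1))


def count_states(profile: OrderProfile, min_dwell: int = 100) -> int:
    """Number of distinct k_parallel states occupied for >= ``min_dwell``
    consecutive frames (short transition transients are ignored)."""
    k = np.asarray(profile.k_parallel)
    if len(k) <= min_dwell:
        raise ValueError("series shorter than min_dwell")
    occupied = set()
    start = 0
    for t in range(1, len(k) + 1):
        if t == len(k) or k[t] != k[start]:
            if t - start >= min_dwell:
                occupied.add(int(k[start]))
            start = t
    return len(occupied)


def rg_histogram(rg_series, n_bins: int = 50):
    """Normalised density histogram of an Rg series (burn-in already removed)."""
    rg_series = np.asarray(rg_series, dtype=float)
    if len(rg_series) == 0:
        raise ValueError("empty Rg series")
    dens, edges = np.histogram(rg_series, bins=n_bins, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, dens


def count_modes(values, n_bins: int = 50, smooth_sigma: float = 1.5,
                min_prominence: float = 0.08) -> int:
    """Number of persistent modes of a 1D sample distribution.

    Histogram -> mild Gaussian smoothing -> peak finding with a prominence
    of ``min_prominence`` times the density maximum, which ignores shallow
    sampling ripples while keeping genuinely separated modes.
    """
    _, dens = rg_histogram(values, n_bins)
    smooth = gaussian_filter1d(dens, smooth_sigma)
    # zero-pad so a mode sitting on the first/last bin still has two bases
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = signal.find_peaks(padded, prominence=min_prominence * smooth.max())
    return int(len(peaks))


def com_msd(com_series: np.ndarray, times: np.ndarray, n_lags: int = 30):
    """Mean-squared displacement of the centre of mass over all time origins.

    ``times`` must be uniform.  Lags are log-spaced between one sample and
    half the series span.  Returns (lag times, msd).
    """
    com = np.asarray(com_series, dtype=float)
    times = np.asarray(times, dtype=float)
    dt_s = np.diff(times)
    if len(com) < 4 or not np.allclose(dt_s, dt_s[0]):
        raise ValueError("com_msd needs a uniformly sampled series of >= 4 frames")
    max_lag = len(com) // 2
    lags = np.unique(np.geomspace(1, max_lag, n_lags).astype(int))
    msd = np.array(
        [np.mean(np.sum((com[lag:] - com[:-lag]) ** 2, axis=1)) for lag in lags]
    )
    return lags * dt_s[0], msd


def swelling_ratio(rg_active_mean: float, rg_passive_mean: float) -> float:
    """Time-averaged Rg at a given activity over the passive reference
    (fa = 0, kBT = 1) of the same topology."""
    if rg_passive_mean <= 0:
        raise ValueError("passive reference Rg must be positive")
    return rg_active_mean / rg_passive_mean


def time_average(series: np.ndarray, burn_in: float = 0.1) -> float:
    """Mean of a series after discarding the leading ``burn_in`` fraction."""
    series = np.asarray(series, dtype=float)
    start = int(np.floor(burn_in * len(series)))
    return float(np.nanmean(series[start:]))
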