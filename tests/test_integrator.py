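import numpy as np
import pytest
from scipy import stats

from activestar import (
    ActivityParams,
    SimulationParams,
    build_chain,
    build_star,
    com_msd,
    continue_run,
    random_forces,
    run,
    step,
)
from activestar.topology import SystemState, initial_conformation

from conftest import passive_params


def fit_diffusivity(com, times, lag_lo, lag_hi):
    """Slope-based D estimate, immune to the constant inertial offset of
    the underdamped MSD (MSD = 6D(t - tau_m(1 - exp(-t/tau_m))))."""
    lags, msd = com_msd(com, times, n_lags=40)
    m = (lags >= lag_lo) & (lags <= lag_hi)
    slope = np.polyfit(lags[m], msd[m], 1)[0]
    return slope / 6.0


class TestRandomForces:
    def test_zero_temperature_means_zero_force(self, rng):
        assert np.all(random_forces(10, 0.0, 1.0, 1e-3, rng) == 0.0)

    def test_variance_matches_fluctuation_dissipation(self, rng):
        # per-component variance 2 kBT gamma / dt = 2000 at the run parameters
        f = random_forces(350_000, 1.0, 1.0, 1e-3, rng)
        var = f.var(axis=0)
        se = 2000.0 * np.sqrt(2 / f.shape[0])
        assert np.all(np.abs(var - 2000.0) < 4 * se)
        se_mean = np.sqrt(2000.0 / f.shape[0])
        assert np.all(np.abs(f.mean(axis=0)) < 4 * se_mean)


class TestParams:
    def test_dt_cap_enforced_and_overridable(self):
        with pytest.raises(ValueError, match="cap"):
            passive_params(dt=2e-3)
        p = passive_params(dt=2e-3, enforce_dt_max=False)
        assert p.dt == 2e-3

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            passive_params(mass=0.0)
        with pytest.raises(ValueError):
            passive_params(dt=-1e-3)
        with pytest.raises(ValueError):
            passive_params(sample_every=0)


class TestRunContract:
    def test_zero_steps_returns_initial_state(self, small_star):
        p = passive_params(n_steps=0, seed=3)
        s0 = initial_conformation(small_star, seed=3)
        traj, _ = run(p, small_star, state=s0)
        assert np.array_equal(traj.final_state.positions, s0.positions)
        assert np.array_equal(traj.final_state.velocities, s0.velocities)
        assert len(traj) == 1

    def test_same_seed_reproduces_observables(self, small_star):
        p = passive_params(n_steps=5000, sample_every=500, seed=11)
        t1, _ = run(p, small_star)
        t2, _ = run(p, small_star)
        assert np.array_equal(t1.rg, t2.rg)
        assert np.array_equal(t1.final_state.positions, t2.final_state.positions)

    def test_checkpoint_restart_is_bitwise_identical(self, small_star):
        full = passive_params(n_steps=4000, sample_every=500, seed=13)
        t_full, _ = run(full, small_star)

        first = passive_params(n_steps=2000, sample_every=500, seed=13)
        _, cp = run(first, small_star)
        t_rest, _ = continue_run(first, small_star, cp, extra_steps=2000)
        assert np.array_equal(t_full.final_state.positions, t_rest.final_state.positions)
        assert np.array_equal(t_full.rg[4:], t_rest.rg)

    def test_observers_called_every_stride(self, small_star):
        calls = []
        p = passive_params(n_steps=2000, sample_every=400, seed=1)
        run(p, small_star, observers=(lambda i, s: calls.append(i),))
        assert calls == [400, 800, 1200, 1600, 2000]

    def test_step_reference_advances_time_and_stays_finite(self, small_star, rng):
        p = passive_params(dt=1e-3, seed=1)
        s = initial_conformation(small_star, seed=1)
        out = step(s, p, small_star, rng)
        assert out.time == pytest.approx(1e-3)
        assert np.isfinite(out.positions).all()
        assert not np.allclose(out.positions, s.positions)


class TestThermalEquilibrium:
    def test_velocity_distribution_is_maxwellian(self, free_bead_topology):
        # free bead, kBT=1: each velocity component Gaussian, variance kBT/m
        p = passive_params(dt=1e-3, n_steps=2_000_000, sample_every=20, seed=8)
        st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)))
        samples = []
        run(p, free_bead_topology, state=st,
            observers=(lambda i, s: samples.append(s.velocities[0].copy()),))
        v = np.array(samples[500:])
        assert v.shape[0] >= 99_000
        # thin to independent samples: velocity decorrelates over m/gamma = 1,
        # keep one sample every 5 time units
        vx = v[::250, 0]
        ks = stats.kstest(vx, "norm", args=(0, 1.0))
        assert ks.pvalue > 0.01
        assert np.isclose(v.var(), 1.0, rtol=0.05)

    def test_dimer_equipartition(self):
        # one vibrational mode: <U_bond> = kBT/2; kinetic: 3 kBT/2 per bead
        t = build_chain(2)
        p = passive_params(dt=1e-3, n_steps=1_500_000, sample_every=150, seed=21)
        bond_e = []

        def obs(i, s):
            l = np.linalg.norm(s.positions[1] - s.positions[0])
            bond_e.append(0.5e4 * (l - 1.0) ** 2)

        traj, _ = run(p, t, observers=(obs,))
        be = np.array(bond_e[len(bond_e) // 5 :])
        ke = traj.kinetic_per_bead[len(traj) // 5 :]
        assert np.isclose(ke.mean(), 1.5, rtol=0.05)
        # stiff-mode discretization runs slightly hot at omega*dt ~ 0.14
        assert np.isclose(be.mean(), 0.5, rtol=0.12)

    def test_free_bead_einstein_relation(self, free_bead_topology):
        # D = kBT/gamma = 1 from the long-lag MSD slope
        Ds = []
        for seed in (1, 2, 3):
            p = passive_params(dt=1e-3, n_steps=7_000_000, sample_every=1000, seed=seed)
            st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)))
            traj, _ = run(p, free_bead_topology, state=st)
            Ds.append(fit_diffusivity(traj.com, traj.times, 5, 100))
        assert np.mean(Ds) == pytest.approx(1.0, rel=0.10)


class TestActiveOracles:
    def test_single_abp_effective_diffusivity(self, free_bead_topology):
        # overdamped closed form D_eff = kBT/gamma + fa^2/(6 gamma^2 Dr);
        # fa/kBT = 50 keeps the persistence time 1/(2 Dr) short enough for
        # tight MSD statistics while activity still dominates (D_eff ~ 140 D)
        act = ActivityParams(model="abp", fa=1.0, kBT=1 / 50)
        expected = act.D + 1.0 / (6 * act.Dr)
        Ds = []
        for seed in (1, 2, 3):
            p = SimulationParams(activity=act, dt=1e-3, n_steps=10_000_000,
                                 sample_every=1000, seed=seed)
            st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)))
            traj, _ = run(p, free_bead_topology, state=st)
            # fit well beyond the persistence time 1/(2 Dr) = 8.3
            Ds.append(fit_diffusivity(traj.com, traj.times, 30, 250))
        assert np.mean(Ds) == pytest.approx(expected, rel=0.10)

    def test_velocity_aligned_terminal_speed(self, free_bead_topology):
        # low kBT: stationary speed concentrates near fa/gamma = 1
        act = ActivityParams(model="velocity_aligned", fa=1.0, kBT=0.005)
        p = SimulationParams(activity=act, dt=1e-3, n_steps=400_000,
                             sample_every=400, seed=5)
        st = SystemState(np.zeros((1, 3)), np.array([[0.1, 0.0, 0.0]]))
        speeds = []
        run(p, free_bead_topology, state=st,
            observers=(lambda i, s: speeds.append(np.linalg.norm(s.velocities[0])),))
        assert np.mean(speeds[200:]) == pytest.approx(1.0, rel=0.10)

    def test_abp_swelling_grows_with_activity(self):
        # uncorrelated activity swells the star monotonically (no transition)
        t = build_star(3, 8)
        means = []
        for ratio in (10.0, 300.0):
            rgs = []
            for seed in (3, 4):
                act = ActivityParams(model="abp", fa=1.0, kBT=1.0 / ratio)
                p = SimulationParams(activity=act, dt=5e-4, n_steps=800_000,
                                     sample_every=2000, seed=seed)
                traj, _ = run(p, t)
                rgs.append(np.mean(traj.rg[len(traj.rg) // 3:]))
            means.append(np.mean(rgs))
        assert means[1] > means[0]

    def test_kinetic_energy_stays_bounded_under_drive(self):
        # driven system: no energy conservation, but no blow-up either
        t = build_star(3, 10)
        act = ActivityParams(model="velocity_aligned", fa=1.0, kBT=1 / 300)
        p = SimulationParams(activity=act, dt=5e-4, n_steps=1_000_000,
                             sample_every=1000, seed=9)
        traj, _ = run(p, t)
        # per-bead KE of order 1/2 m (fa/gamma)^2 = 0.5; far below any runaway
        assert np.all(traj.kinetic_per_bead < 50.0)
        assert np.isfinite(traj.final_state.positions).all()


def test_nonfinite_state_raises_with_diagnostic(small_star):
    p = passive_params(dt=1e-3, n_steps=1000, sample_every=100, seed=1)
    s = initial_conformation(small_star, seed=1)
    s.velocities[2] = 1e155  # force an overflow inside the kernel
    with pytest.raises(FloatingPointError, match="non-finite"):
        run(p, small_star, state=s)
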