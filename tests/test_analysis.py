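import numpy as np
import pytest

from activestar import (
    build_star,
    classify_arm_states,
    com_msd,
    count_modes,
    count_states,
    fit_scaling_exponent,
    g_factor,
    order_parameter,
    radius_of_gyration,
    rg_histogram,
    swelling_ratio,
    time_average,
)
from activestar.analysis import OrderProfile
from activestar.scenarios import synthetic_velocity_field
from activestar.topology import SystemState


class TestRadiusOfGyration:
    def test_symmetric_dumbbell(self):
        assert radius_of_gyration([[0, 0, 0], [2, 0, 0]]) == pytest.approx(1.0)

    def test_three_collinear_beads(self):
        rg = radius_of_gyration([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert rg == pytest.approx(np.sqrt(2 / 3))

    def test_rigid_motion_invariance(self, rng):
        pos = rng.normal(size=(20, 3))
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = pos @ R.T + np.array([5.0, -3.0, 2.0])
        assert radius_of_gyration(moved) == pytest.approx(radius_of_gyration(pos))

    def test_single_bead_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration([[0, 0, 0]])


class TestGFactor:
    def test_identity_and_arithmetic(self):
        assert g_factor(2.0, 2.0) == 1.0
        assert g_factor(2.0, 4.0) == 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            g_factor(0.0, 1.0)


class TestScalingFit:
    @pytest.mark.parametrize("nu", [0.6, 1.0])
    def test_exact_power_law_recovered(self, nu):
        sizes = np.array([31, 61, 121, 241])
        rg = 0.42 * sizes.astype(float) ** nu
        slope, stderr = fit_scaling_exponent(sizes, rg)
        assert slope == pytest.approx(nu, abs=1e-12)
        assert stderr == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling_exponent([10, 10, 10], [1, 1, 1])
        with pytest.raises(ValueError):
            fit_scaling_exponent([10, 20], [1, 2])


class TestOrderParameter:
    def test_parallel_field_gives_one(self):
        t = build_star(3, 8)
        s = synthetic_velocity_field(t, "parallel")
        g, per = order_parameter(s, t)
        assert g == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(per, 1.0)

    def test_perpendicular_field_gives_zero(self):
        t = build_star(3, 8)
        s = synthetic_velocity_field(t, "perpendicular")
        g, per = order_parameter(s, t)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(per, 0.0)

    def test_isotropic_field_gives_half(self):
        # E|cos(theta)| = 1/2 on the sphere
        t = build_star(4, 25_000)
        s = synthetic_velocity_field(t, "isotropic", seed=2)
        g, _ = order_parameter(s, t)
        # s.e. of the per-bead average of |cos|: std ~ 0.29/sqrt(n)
        assert g == pytest.approx(0.5, abs=3 * 0.29 / np.sqrt(t.n_beads))

    def test_mixed_field_per_arm_split(self):
        t = build_star(3, 8)
        s = synthetic_velocity_field(t, "mixed", k=1)
        _, per = order_parameter(s, t)
        assert per[0] == pytest.approx(1.0)
        assert per[1] == pytest.approx(0.0)
        assert per[2] == pytest.approx(0.0)

    def test_all_beads_at_rest_rejected(self):
        t = build_star(3, 2)
        s = SystemState(synthetic_velocity_field(t, "parallel").positions,
                        np.zeros((t.n_beads, 3)))
        with pytest.raises(ValueError, match="order parameter undefined"):
            order_parameter(s, t)


class TestArmStates:
    def test_thresholds_label_extremes(self):
        series = np.full((300, 3), 0.9)
        prof = classify_arm_states(series)
        assert np.all(prof.k_parallel == 3)
        prof = classify_arm_states(np.full((300, 3), 0.05))
        assert np.all(prof.k_parallel == 0)

    def test_mixed_arms_counted(self):
        series = np.tile([0.9, 0.1, 0.1], (300, 1))
        prof = classify_arm_states(series)
        assert np.all(prof.k_parallel == 1)
        assert set(np.unique(prof.arm_states)) == {-1, 1}

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_arm_states(np.zeros((10, 2)), thresholds=(0.8, 0.2))

    def test_count_states_with_dwell_filter(self):
        k = np.concatenate([np.zeros(500), np.full(3, 2), np.full(500, 3),
                            np.zeros(500), np.full(500, 3)])
        prof = OrderProfile(arm_states=np.zeros((len(k), 3)), k_parallel=k.astype(int))
        # the 3-frame excursion to k=2 is a transition transient
        assert count_states(prof, min_dwell=100) == 2

    def test_constant_series_is_one_state(self):
        prof = OrderProfile(np.zeros((400, 3)), np.full(400, 2))
        assert count_states(prof, min_dwell=100) == 1
        with pytest.raises(ValueError):
            count_states(prof, min_dwell=400)


class TestHistogramAndModes:
    def test_density_normalisation(self, rng):
        centers, dens = rg_histogram(rng.normal(5.0, 1.0, size=5000), n_bins=40)
        width = centers[1] - centers[0]
        assert np.sum(dens) * width == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_single_bin(self):
        centers, dens = rg_histogram(np.full(200, 3.0), n_bins=10)
        assert np.count_nonzero(dens) == 1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            rg_histogram([])

    def test_mixture_modes_detected(self, rng):
        uni = rng.normal(5.0, 0.5, size=4000)
        bi = np.concatenate([rng.normal(3.0, 0.4, 2000), rng.normal(7.0, 0.4, 2000)])
        assert count_modes(uni) == 1
        assert count_modes(bi) == 2


class TestComMSD:
    def test_ballistic_motion(self):
        times = np.arange(200) * 0.5
        v = np.array([0.3, -0.2, 0.1])
        com = times[:, None] * v
        lags, msd = com_msd(com, times)
        assert np.allclose(msd, np.sum(v**2) * lags**2, rtol=1e-10)
        # log-log slope 2
        sl = np.polyfit(np.log(lags), np.log(msd), 1)[0]
        assert sl == pytest.approx(2.0, abs=1e-8)

    def test_zero_motion(self):
        times = np.arange(100) * 1.0
        lags, msd = com_msd(np.zeros((100, 3)), times)
        assert np.allclose(msd, 0.0)

    def test_nonuniform_sampling_rejected(self):
        times = np.array([0.0, 1.0, 3.0, 7.0, 8.0])
        with pytest.raises(ValueError):
            com_msd(np.zeros((5, 3)), times)


def test_swelling_ratio_and_time_average():
    assert swelling_ratio(6.0, 4.0) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        swelling_ratio(1.0, 0.0)
    series = np.concatenate([np.full(10, 99.0), np.full(90, 2.0)])
    assert time_average(series, burn_in=0.1) == pytest.approx(2.0)
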