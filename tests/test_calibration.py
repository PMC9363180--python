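"""Fit metrics, forward model, and the two-stage calibration."""

import math

import numpy as np
import pytest

from hillhip.calibration import (
    GAConfig,
    GaitTrajectory,
    InfeasibilityError,
    back_solve_activation,
    calibrate,
    forward_moment,
    h_bounds,
    optimize_H,
    optimize_I,
    periodic_derivative,
    r_squared,
    rmse,
    solve_mtu_kinetics,
)
from hillhip.hip_geometry import MUSCLES, FLEXORS, HipModelParams
from hillhip.synthetic_gait import generate_from_model, generate_gait
from hillhip import GaitGenConfig
from conftest import TEST_GA


# ---------------------------------------------------------------------------
# metrics against independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_rmse(a, b, mass):
    s = 0.0
    for x, y in zip(a, b):
        s += (x - y) ** 2
    return math.sqrt(s / len(a)) / mass


def brute_pearson_r2(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov * cov / (va * vb)


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        n = 7
        a = np.arange(n, dtype=float)
        assert rmse(a + 0.5 * 70.0, a, body_mass=70.0) == pytest.approx(0.5)
        assert rmse([1, 2, 3], [2, 2, 2], 1.0) == pytest.approx(math.sqrt(2 / 3))

    def test_rmse_shape_error(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    def test_r2_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(x, 3.0 * x + 1.0) == pytest.approx(1.0)
        assert r_squared([1, 2, 3], [1, 2, 2]) == pytest.approx(0.75)

    def test_r2_degenerate_input(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_r2_cod_variant(self):
        ref = np.array([1.0, 2.0, 3.0])
        model = ref + 0.1
        expected = 1.0 - np.sum(0.01 * np.ones(3)) / np.sum((ref - 2.0) ** 2)
        assert r_squared(model, ref, kind="cod") == pytest.approx(expected)

    def test_metrics_match_brute_force_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(3, 40)
            a = rng.normal(size=n) * 10
            b = a + rng.normal(size=n)
            mass = rng.uniform(40, 100)
            assert rmse(a, b, mass) == pytest.approx(brute_rmse(a, b, mass), abs=1e-12)
            assert r_squared(a, b) == pytest.approx(brute_pearson_r2(list(a), list(b)), abs=1e-12)

    def test_periodic_derivative_against_loop_oracle(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=12)
        x = np.concatenate([u, u[:1]])
        dt = 0.1
        d = periodic_derivative(x, dt)
        for i in range(12):
            expected = (u[(i + 1) % 12] - u[(i - 1) % 12]) / (2 * dt)
            assert d[i] == pytest.approx(expected, abs=1e-14)
        assert d[-1] == d[0]


# ---------------------------------------------------------------------------
# gait container
# ---------------------------------------------------------------------------

class TestGaitTrajectory:
    def test_rejects_bad_grid_and_bounds(self, default_gait):
        with pytest.raises(ValueError):
            GaitTrajectory(
                grid=np.array([0.0, 50.0, 99.0]), time_scale=1.0,
                hip_angle=np.zeros(3), knee_angle=np.zeros(3), hip_moment=np.zeros(3),
                activations={m: np.zeros(3) for m in MUSCLES},
            )
        bad_act = {m: default_gait.activations[m].copy() for m in MUSCLES}
        bad_act["iliopsoas"] = bad_act["iliopsoas"] + 2.0
        with pytest.raises(ValueError):
            GaitTrajectory(
                grid=default_gait.grid, time_scale=1.1,
                hip_angle=default_gait.hip_angle, knee_angle=default_gait.knee_angle,
                hip_moment=default_gait.hip_moment, activations=bad_act,
            )

    def test_nonperiodic_channel_warns(self, default_gait):
        hip = default_gait.hip_angle.copy()
        hip[-1] += 0.1
        with pytest.warns(UserWarning):
            GaitTrajectory(
                grid=default_gait.grid, time_scale=1.1, hip_angle=hip,
                knee_angle=default_gait.knee_angle, hip_moment=default_gait.hip_moment,
                activations=default_gait.activations,
            )


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def constant_pose_gait(n=21, delta=0.0, eta=0.0, act=0.0):
    grid = np.linspace(0, 100, n)
    const = np.full(n, 1.0)
    return GaitTrajectory(
        grid=grid, time_scale=1.0,
        hip_angle=delta * const, knee_angle=eta * const, hip_moment=0.0 * const,
        activations={m: act * const for m in MUSCLES},
    )


class TestForwardMoment:
    def test_deterministic_and_residual_tolerance(self, default_gait, muscles, anthro):
        model = HipModelParams.neutral()
        f1 = forward_moment(default_gait, model, muscles, anthro)
        f2 = forward_moment(default_gait, model, muscles, anthro)
        assert np.array_equal(f1.m_mo, f2.m_mo)
        assert f1.m_mo.shape == default_gait.grid.shape
        for m in MUSCLES:
            assert np.max(np.abs(f1.residual[m])) < 1e-8

    def test_zero_activation_neutral_pose_gives_passive_only(self, muscles, anthro):
        gait = constant_pose_gait()
        model = HipModelParams.neutral()
        fwd = forward_moment(gait, model, muscles, anthro)
        # fibers at optimum, tendons at slack: no force, M_mo = -M_p = 0
        assert np.allclose(fwd.m_mo, 0.0, atol=1e-6)
        for m in MUSCLES:
            assert np.allclose(fwd.force[m], 0.0, atol=1e-4)

    def test_flexor_scale_multiplies_flexor_moments(self, default_gait, muscles, anthro):
        m1 = HipModelParams.neutral()
        m2 = HipModelParams.neutral()
        m2.m_scale = 1.2
        f1 = forward_moment(default_gait, m1, muscles, anthro)
        f2 = forward_moment(default_gait, m2, muscles, anthro)
        for m in FLEXORS:
            assert np.allclose(f2.moment[m], 1.2 * f1.moment[m], rtol=1e-12)

    def test_velocity_is_central_difference_of_fiber_length(self, default_gait, muscles, anthro):
        kin = solve_mtu_kinetics(default_gait, muscles, anthro)
        dt = default_gait.dt
        assert np.max(np.abs(kin.v_mut + periodic_derivative(kin.l_mut, dt))) < 1e-5


# ---------------------------------------------------------------------------
# two-stage calibration
# ---------------------------------------------------------------------------

class TestOptimizeH:
    def test_ga_respects_bounds_and_is_seed_deterministic(self, model_gait, muscles, anthro):
        gait, _ = model_gait
        tiny = GAConfig(population=10, generations=5)
        r1 = optimize_H(gait, muscles, anthro, ga_config=tiny, seed=2, polish=False)
        r2 = optimize_H(gait, muscles, anthro, ga_config=tiny, seed=2, polish=False)
        assert np.array_equal(r1.h_opt, r2.h_opt)
        bounds = h_bounds()
        assert np.all(r1.h_opt >= bounds[:, 0] - 1e-12)
        assert np.all(r1.h_opt <= bounds[:, 1] + 1e-12)

    def test_best_objective_non_increasing_over_generations(self, model_gait, muscles, anthro):
        gait, _ = model_gait
        r = optimize_H(gait, muscles, anthro, ga_config=GAConfig(population=16, generations=20),
                       seed=4, polish=False)
        assert np.all(np.diff(r.history) <= 1e-15)

    def test_invalid_ga_config(self):
        with pytest.raises(ValueError):
            GAConfig(population=1)
        with pytest.raises(ValueError):
            GAConfig(generations=0)

    def test_recovers_scaling_variables_on_noiseless_data(self, recovery_calibration, truth_model):
        c = recovery_calibration
        assert c.rmse < 0.01
        assert abs(c.h_opt[6] - truth_model.m_scale) < 0.05
        assert abs(c.h_opt[7] - truth_model.n_scale) < 0.05

    def test_differential_evolution_alternative(self, model_gait, muscles, anthro):
        gait, _ = model_gait
        r = optimize_H(gait, muscles, anthro, ga_config=GAConfig(population=16, generations=10),
                       seed=1, method="de")
        assert r.rmse < 0.01  # the least-squares polish finishes the job


class TestOptimizeI:
    def test_recovers_fiber_length_off_grid(self, model_gait, truth_model, muscles, anthro):
        """Truth deliberately not a grid point: refinement must still find it."""
        gait, _ = model_gait
        r = optimize_I(gait, truth_model, muscles, anthro, bounds_frac=(0.6123, 1.391))
        for m in MUSCLES:
            assert abs(r.l0[m] - muscles[m].l0m) <= max(r.resolution[m], 1e-6 * muscles[m].l0m)

    def test_reconstructed_activations_feasible_and_match(self, model_gait, truth_model, muscles, anthro):
        gait, _ = model_gait
        r = optimize_I(gait, truth_model, muscles, anthro)
        for m in MUSCLES:
            b = r.activations[m]
            assert np.all(b >= -1e-9) and np.all(b <= 1 + 1e-9)
            assert np.max(np.abs(b - gait.activations[m])) < 1e-4

    def test_infeasible_bounds_raise_naming_muscle(self, model_gait, truth_model, muscles, anthro):
        gait, _ = model_gait
        with pytest.raises(InfeasibilityError) as exc:
            optimize_I(gait, truth_model, muscles, anthro, bounds_frac=(3.0, 3.5), grid_points=11)
        assert exc.value.muscle in MUSCLES

    def test_literal_objective_selects_feasibility_edge(self, model_gait, truth_model, muscles, anthro):
        """The minimum-b_min objective lands at a smaller l0 than the truth."""
        gait, _ = model_gait
        r = optimize_I(gait, truth_model, muscles, anthro, objective="min-bmin")
        assert all(r.l0[m] <= muscles[m].l0m + 1e-9 for m in MUSCLES)
        assert any(r.b_min[m] < 0.01 for m in MUSCLES)

    def test_back_solve_inverts_forward_forces(self, model_gait, truth_model, muscles, anthro):
        gait, truth = model_gait
        fwd = truth.forward
        for m in MUSCLES:
            b = back_solve_activation(
                fwd.force[m], fwd.l_mt[m], muscles[m], fwd.fmax_eff[m], gait.dt
            )
            assert np.max(np.abs(b - gait.activations[m])) < 1e-6


class TestFullCalibration:
    def test_recovery_and_self_consistency(self, recovery_calibration, model_gait, muscles):
        gait, _ = model_gait
        c = recovery_calibration
        assert c.r2 > 0.999
        for m in MUSCLES:
            assert abs(c.i_opt[m] - muscles[m].l0m) <= max(c.i_resolution[m], 1e-6)
            assert 0.0 <= c.b_min_per_muscle[m] <= 1.0
        assert c.model_moment.shape == gait.grid.shape

    def test_noise_floor_bounds_achievable_fit(self, truth_model, muscles, anthro, default_gait):
        clean, _ = generate_from_model(truth_model, muscles, anthro, default_gait)
        noisy, _ = generate_from_model(
            truth_model, muscles, anthro, default_gait, noise_sd=0.05, seed=17
        )
        floor = rmse(noisy.hip_moment, clean.hip_moment, anthro.body_mass)
        c = calibrate(noisy, muscles, anthro, ga_config=TEST_GA, seed=9)
        assert c.rmse < 2.0 * floor
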