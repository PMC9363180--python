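"""EET spring law, residual moments, redistribution, and sweep shape."""

import numpy as np
import pytest

from hillhip.eet_assist import (
    DEFAULT_SWEEP,
    EETConfig,
    eet_moment,
    flexor_total,
    mdc,
    muscle_power,
    redistribute,
    residual_moments,
    stiffness_sweep,
    work_components,
)
from hillhip.hip_geometry import EXTENSORS, FLEXORS, MUSCLES


class TestEETMoment:
    def test_zero_on_flexion_side(self):
        d = np.linspace(0.0, 0.5, 20)
        assert np.all(eet_moment(d, 300.0) == 0.0)

    def test_zero_stiffness(self):
        d = np.linspace(-0.3, 0.5, 20)
        assert np.all(eet_moment(d, 0.0) == 0.0)

    def test_magnitude_example(self):
        assert eet_moment(-0.2, 200.0) == pytest.approx(40.0)

    def test_linear_in_stiffness(self):
        d = np.linspace(-0.3, 0.3, 41)
        assert np.allclose(eet_moment(d, 3.0 * 150.0), 3.0 * eet_moment(d, 150.0))

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ValueError):
            eet_moment(-0.1, -5.0)
        with pytest.raises(ValueError):
            EETConfig(stiffness=-1.0)
        with pytest.raises(ValueError):
            EETConfig(sweep=(100.0, 50.0))


class TestResidualMoments:
    @pytest.mark.parametrize(
        "m_t, m_j, expect_re, expect_ex",
        [(50.0, 20.0, 30.0, 0.0), (50.0, 50.0, 0.0, 0.0), (50.0, 60.0, 0.0, -10.0)],
    )
    def test_branches(self, m_t, m_j, expect_re, expect_ex):
        re, ex = residual_moments(np.array([m_t]), np.array([m_j]))
        assert re[0] == pytest.approx(expect_re)
        assert ex[0] == pytest.approx(expect_ex)

    def test_continuity_at_switch(self):
        m_t = np.full(3, 40.0)
        eps = 1e-9
        re_lo, ex_lo = residual_moments(m_t, np.array([40 - eps] * 3))
        re_hi, ex_hi = residual_moments(m_t, np.array([40 + eps] * 3))
        assert np.all(np.abs(re_lo - re_hi) < 1e-8)
        assert np.all(np.abs(ex_lo - ex_hi) < 1e-8)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            residual_moments(np.ones(3), np.ones(4))


class TestMDC:
    def test_single_active_member_takes_all(self):
        grid = np.linspace(0, 100, 11)
        out = mdc({"a": np.ones(11), "b": np.zeros(11)}, grid, (0, 100))
        assert out == {"a": 1.0, "b": 0.0}

    def test_equal_traces_split_evenly(self):
        grid = np.linspace(0, 100, 11)
        v = np.abs(np.sin(grid / 10)) + 0.1
        out = mdc({"a": v, "b": v.copy()}, grid, (10, 90))
        assert out["a"] == pytest.approx(0.5)

    def test_ratio_of_integrals(self):
        grid = np.linspace(0, 100, 101)
        out = mdc({"a": np.full(101, 30.0), "b": np.full(101, 10.0)}, grid, (0, 100))
        assert out["a"] == pytest.approx(0.75)
        assert out["b"] == pytest.approx(0.25)

    def test_zero_group_flagged_undefined(self):
        grid = np.linspace(0, 100, 11)
        out = mdc({"a": np.zeros(11), "b": np.zeros(11)}, grid, (0, 100))
        assert all(np.isnan(v) for v in out.values())

    def test_bad_windows_raise(self):
        grid = np.linspace(0, 100, 11)
        with pytest.raises(ValueError):
            mdc({"a": np.ones(11), "b": np.ones(11)}, grid, (60, 60))
        with pytest.raises(ValueError):
            mdc({"a": np.ones(11), "b": np.ones(11)}, grid, (90, 120))


class TestMusclePower:
    def test_examples_and_sign(self):
        assert muscle_power(100.0, 0.0) == 0.0
        assert muscle_power(100.0, 0.1) == pytest.approx(10.0)
        assert muscle_power(100.0, -0.1) == pytest.approx(-10.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            muscle_power(np.ones(3), np.ones(4))


class TestRedistribute:
    def test_zero_stiffness_reproduces_baseline(
        self, default_gait, default_calibration, default_baseline, anthro
    ):
        r = redistribute(default_gait, default_calibration, 0.0, anthro,
                         baseline=default_baseline)
        for m in MUSCLES:
            assert np.array_equal(r.moment[m], default_baseline.moment[m])
            assert np.array_equal(r.force[m], default_baseline.force[m])
            # back-solved activation inherits the velocity-consistency
            # tolerance of the forward solve through the eccentric fv slope
            assert np.max(np.abs(r.activations[m] - default_gait.activations[m])) < 1e-5
        assert np.all(r.assist_moment == 0.0)
        assert np.all(r.extensor_resistance == 0.0)

    def test_flexor_conservation_at_every_sample(
        self, default_gait, default_calibration, default_baseline, anthro
    ):
        for j in (100.0, 300.0, 600.0):
            r = redistribute(default_gait, default_calibration, j, anthro,
                             baseline=default_baseline)
            flex_sum = sum(r.moment[m] for m in FLEXORS)
            scale = max(1.0, np.abs(r.residual_flexion).max())
            assert np.max(np.abs(flex_sum - r.residual_flexion)) < 1e-9 * scale
            ext_demand = sum(default_baseline.moment[m] for m in EXTENSORS) + np.abs(
                r.extensor_resistance
            )
            ext_sum = sum(r.moment[m] for m in EXTENSORS)
            assert np.max(np.abs(ext_sum - ext_demand)) < 1e-9 * max(1.0, ext_demand.max())

    def test_conservation_m_re_plus_m_j_equals_m_t(
        self, default_gait, default_calibration, default_baseline, anthro
    ):
        r = redistribute(default_gait, default_calibration, 150.0, anthro,
                         baseline=default_baseline)
        m_t = flexor_total(default_baseline)
        sub = r.assist_moment <= m_t
        assert np.max(np.abs((r.residual_flexion + r.assist_moment - m_t)[sub])) < 1e-9

    def test_mdc_in_unit_interval_and_sums_to_one(
        self, default_gait, default_calibration, default_baseline, anthro
    ):
        r = redistribute(default_gait, default_calibration, 200.0, anthro,
                         baseline=default_baseline)
        for group in (r.mdc_flexor, r.mdc_extensor):
            vals = list(group.values())
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert sum(vals) == pytest.approx(1.0)

    def test_work_decomposition_identity(
        self, default_gait, default_calibration, default_baseline, anthro
    ):
        for j in (0.0, 250.0):
            r = redistribute(default_gait, default_calibration, j, anthro,
                             baseline=default_baseline)
            w = work_components(r)
            assert w["mtu"] == pytest.approx(w["fiber"] + w["tendon"], abs=1e-6)
            # elastic tendon over one periodic cycle nets ~ no work
            assert abs(w["tendon"]) < 1e-6


class TestStiffnessSweep:
    def test_summary_is_deterministic_and_baseline_first(
        self, default_gait, default_calibration, anthro
    ):
        t1, r1 = stiffness_sweep(default_gait, default_calibration, (0.0, 100.0), anthro)
        t2, r2 = stiffness_sweep(default_gait, default_calibration, (0.0, 100.0), anthro)
        assert t1.equals(t2)
        assert t1.loc[0, "assist_moment_peak"] == 0.0

    def test_assist_engages_only_in_extension_window(
        self, default_gait, default_calibration, anthro
    ):
        _, results = stiffness_sweep(default_gait, default_calibration, (0.0, 400.0), anthro)
        r = results[1]
        engaged = default_gait.hip_angle < 0
        assert np.all(r.assist_moment[~engaged] == 0.0)
        assert np.all(r.assist_moment[engaged] > 0.0)

    def test_residual_flexor_monotone_then_extensor_penalty(
        self, default_gait, default_calibration, anthro
    ):
        table, results = stiffness_sweep(default_gait, default_calibration, DEFAULT_SWEEP, anthro)
        m_t = results[0].flexor_total_unassisted
        window = results[0].window
        mask = (default_gait.grid >= window[0]) & (default_gait.grid <= window[1])
        # index of the first stiffness where the assist exceeds the flexor total
        crossover = len(DEFAULT_SWEEP)
        for i, r in enumerate(results):
            if np.any(r.assist_moment[mask] > m_t[mask]):
                crossover = i
                break
        res = table["residual_flexor_window_mean"].to_numpy()
        ext = table["extensor_total_window_mean"].to_numpy()
        assert np.all(np.diff(res) <= 1e-9)  # non-increasing throughout (Eq 21 clamps at 0)
        assert np.all(np.diff(ext[max(crossover - 1, 0):]) >= -1e-9)
        assert crossover < len(DEFAULT_SWEEP)  # the default sweep does reach the switch

    def test_sweep_rejects_empty_or_unsorted(self, default_gait, default_calibration, anthro):
        with pytest.raises(ValueError):
            stiffness_sweep(default_gait, default_calibration, (), anthro)
        with pytest.raises(ValueError):
            stiffness_sweep(default_gait, default_calibration, (100.0, 50.0), anthro)
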