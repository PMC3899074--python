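"""Bulk acoustics: substitution-method exactness, surface detection on
simulated scans, attenuation recovery, and serial-contour volumetry."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from susi.bulk import (
    EchoTimes,
    attenuation_coefficient,
    construct_volume,
    detect_surfaces,
    thickness_and_speed,
)
from susi.rf import AcquisitionGrid, BModeImage, MediumSpec
from susi.simulate import PhantomConfig, simulate_scan


def forward_times(thickness_mm, c_t, standoff_mm=2.0, gelpad_mm=4.5, c_f=1480.0):
    """Time-of-flight forward model used as the independent oracle."""
    t_top = 2 * standoff_mm * 1e-3 / c_f
    t_bot = t_top + 2 * thickness_mm * 1e-3 / c_t
    t_gel = t_bot + 2 * (gelpad_mm - standoff_mm - thickness_mm) * 1e-3 / c_f
    t_ref = 2 * gelpad_mm * 1e-3 / c_f
    return EchoTimes(t_top=t_top, t_bot=t_bot, t_gel=t_gel, t_ref=t_ref)


class TestThicknessAndSpeed:
    def test_no_contrast_recovers_fluid_speed(self, medium):
        times = forward_times(1.2, 1480.0)
        thickness, c_t = thickness_and_speed(times, medium)
        assert math.isclose(c_t, 1480.0, rel_tol=1e-12)
        assert math.isclose(thickness, 1.2, rel_tol=1e-12)

    @pytest.mark.parametrize("thickness,c_t", [(1.2, 1540.0), (0.8, 1450.0), (2.0, 1600.0)])
    def test_forward_inverse_exact(self, medium, thickness, c_t):
        est_l, est_c = thickness_and_speed(forward_times(thickness, c_t), medium)
        assert math.isclose(est_l, thickness, rel_tol=1e-12)
        assert math.isclose(est_c, c_t, rel_tol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.3, max_value=2.2),
        st.floats(min_value=1350.0, max_value=1650.0),
    )
    def test_exactness_property(self, thickness, c_t):
        est_l, est_c = thickness_and_speed(forward_times(thickness, c_t), MediumSpec())
        assert math.isclose(est_l, thickness, rel_tol=1e-9)
        assert math.isclose(est_c, c_t, rel_tol=1e-9)

    def test_substitution_identities_hold(self, medium):
        times = forward_times(1.0, 1520.0)
        thickness, c_t = thickness_and_speed(times, medium)
        l_m = thickness * 1e-3
        assert math.isclose(2 * l_m / c_t, times.t_bot - times.t_top, rel_tol=1e-12)
        assert math.isclose(
            2 * l_m / medium.c_fluid,
            (times.t_ref - times.t_gel) + (times.t_bot - times.t_top),
            rel_tol=1e-12,
        )

    def test_nonphysical_times_rejected(self, medium):
        with pytest.raises(ValueError):
            EchoTimes(t_top=1e-6, t_bot=3e-6, t_gel=2e-6, t_ref=3e-6)
        times = EchoTimes(t_top=1e-6, t_bot=2e-6, t_gel=3e-6, t_ref=1.5e-6)
        with pytest.raises(ValueError, match="thickness"):
            thickness_and_speed(times, medium)


class TestDetectSurfaces:
    def test_end_to_end_recovery(self, transducer, medium):
        cfg = PhantomConfig(
            scatterer_diameter_um=14.0,
            number_concentration=1000.0,
            medium_speed=1520.0,
            thickness_mm=1.0,
            standoff_mm=3.0,
            gelpad_depth_mm=4.8,
            rng_seed=11,
        )
        grid = AcquisitionGrid(n_lines=40, n_slices=1)
        sample, ref = simulate_scan(cfg, transducer, grid, medium, seed=11)
        surfaces = detect_surfaces(sample, ref)
        times = surfaces.median()
        dt = sample.grid.axial_dt
        assert abs((times.t_bot - times.t_top) - 2 * 1.0e-3 / 1520.0) <= dt
        thickness, c_t = thickness_and_speed(times, medium)
        sample_dist_mm = dt * medium.c_fluid / 2 * 1e3
        assert abs(thickness - 1.0) <= sample_dist_mm
        assert abs(c_t - 1520.0) <= 0.01 * 1520.0

    def test_reference_time_matches_configuration(self, transducer, medium):
        cfg = PhantomConfig(number_concentration=0.0, thickness_mm=1.0, gelpad_depth_mm=4.0)
        grid = AcquisitionGrid(n_lines=4, n_slices=1)
        sample, ref = simulate_scan(cfg, transducer, grid, medium, seed=2)
        surfaces = detect_surfaces(sample, ref)
        expected = 2 * cfg.gelpad_depth_mm * 1e-3 / medium.c_fluid
        assert abs(surfaces.median().t_ref - expected) <= sample.grid.axial_dt

    def test_threshold_above_echoes_raises(self, transducer, medium):
        cfg = PhantomConfig(number_concentration=0.0, thickness_mm=1.0, gelpad_depth_mm=4.0)
        grid = AcquisitionGrid(n_lines=2, n_slices=1)
        sample, ref = simulate_scan(cfg, transducer, grid, medium, seed=2)
        with pytest.raises(ValueError, match="every A-line"):
            detect_surfaces(sample, ref, threshold_db=0.0)


class TestAttenuation:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0])
    def test_recovery_within_ten_percent(self, transducer, medium, alpha):
        cfg = PhantomConfig(
            scatterer_diameter_um=14.0,
            number_concentration=1000.0,
            attenuation_coeff=alpha,
            thickness_mm=2.0,
            rng_seed=4,
        )
        grid = AcquisitionGrid(n_lines=100, n_slices=1)
        sample, ref = simulate_scan(cfg, transducer, grid, medium, seed=4)
        surfaces = detect_surfaces(sample, ref)
        thickness, _ = thickness_and_speed(surfaces.median(), medium)
        est, _ = attenuation_coefficient(sample, ref, surfaces, thickness)
        assert abs(est - alpha) <= 0.1 * alpha

    def test_zero_attenuation(self, transducer, medium):
        cfg = PhantomConfig(
            scatterer_diameter_um=14.0,
            number_concentration=1000.0,
            attenuation_coeff=0.0,
            thickness_mm=2.0,
        )
        grid = AcquisitionGrid(n_lines=60, n_slices=1)
        sample, ref = simulate_scan(cfg, transducer, grid, medium, seed=5)
        surfaces = detect_surfaces(sample, ref)
        thickness, _ = thickness_and_speed(surfaces.median(), medium)
        est, _ = attenuation_coefficient(sample, ref, surfaces, thickness)
        assert abs(est) <= 0.05

    def test_insertion_loss_doubles_with_thickness(self, transducer, medium):
        """alpha(f) in dB/cm is path-normalized: doubling L leaves it fixed,
        so the raw insertion loss (alpha * 2L) doubles."""
        results = {}
        for thickness, pad in ((1.0, 4.0), (2.0, 5.0)):
            cfg = PhantomConfig(
                number_concentration=0.0,
                attenuation_coeff=0.5,
                thickness_mm=thickness,
                gelpad_depth_mm=pad,
            )
            grid = AcquisitionGrid(n_lines=4, n_slices=1)
            sample, ref = simulate_scan(cfg, transducer, grid, medium, seed=6)
            surfaces = detect_surfaces(sample, ref)
            est, diag = attenuation_coefficient(sample, ref, surfaces, thickness)
            results[thickness] = (est, diag)
        il_1 = results[1.0][1]["alpha_db_per_cm"] * 2 * 0.1  # back to raw dB
        il_2 = results[2.0][1]["alpha_db_per_cm"] * 2 * 0.2
        ratio = np.median(il_2[il_1 > 1.0] / il_1[il_1 > 1.0])
        assert abs(ratio - 2.0) < 0.2


def _disk_bmode_stack(radius_mm, height_mm, n_slices, slice_spacing_um):
    """Synthetic B-mode stack of a vertical cylinder (analytic volume oracle)."""
    axial_dt = 1 / 420e6
    axial_mm = axial_dt * 1480.0 / 2 * 1e3
    lateral_um = 31.0
    n_samples = int(height_mm / axial_mm) + 200
    n_lines = int(2.2 * radius_mm * 1e3 / lateral_um)
    stack = []
    for k in range(n_slices):
        y = (k - (n_slices - 1) / 2) * slice_spacing_um * 1e-3
        chord = math.sqrt(max(radius_mm**2 - y**2, 0.0))
        db = np.full((n_samples, n_lines), -50.0)
        if chord > 0:
            x = (np.arange(n_lines) - (n_lines - 1) / 2) * lateral_um * 1e-3
            cols = np.abs(x) <= chord
            rows = slice(100, 100 + int(round(height_mm / axial_mm)))
            db[rows, cols] = -5.0
        grid = AcquisitionGrid(
            axial_dt=axial_dt,
            lateral_spacing=lateral_um,
            slice_spacing=slice_spacing_um,
            n_samples=n_samples,
            n_lines=n_lines,
            n_slices=n_slices,
        )
        stack.append(BModeImage(db=db, dynamic_range=50.0, grid=grid))
    return stack


class TestConstructVolume:
    def test_cylinder_within_ten_percent(self):
        r, h = 2.0, 1.0
        stack = _disk_bmode_stack(r, h, n_slices=21, slice_spacing_um=200.0)
        est = construct_volume(stack, threshold_db=30.0)
        analytic = math.pi * r**2 * h
        assert abs(est.volume_mm3 - analytic) <= 0.10 * analytic

    def test_noise_only_stack_zero_volume(self):
        axial_dt = 1 / 420e6
        grid = AcquisitionGrid(
            axial_dt=axial_dt, n_samples=128, n_lines=32, n_slices=1
        )
        rng = np.random.default_rng(0)
        db = np.clip(-45 + 3 * rng.standard_normal((128, 32)), -50, 0) * 0 - 45.0
        img = BModeImage(db=db, dynamic_range=50.0, grid=grid)
        est = construct_volume([img], threshold_db=30.0)
        assert est.volume_mm3 == 0.0

    def test_trapezoidal_rule_agrees_on_smooth_solid(self):
        r, h = 2.0, 1.0
        stack = _disk_bmode_stack(r, h, n_slices=21, slice_spacing_um=200.0)
        rect = construct_volume(stack, threshold_db=30.0)
        trap = construct_volume(stack, threshold_db=30.0, rule="trapezoidal")
        analytic = math.pi * r**2 * h
        assert abs(trap.volume_mm3 - analytic) <= 0.10 * analytic
        assert abs(trap.volume_mm3 - rect.volume_mm3) <= 0.05 * analytic
        with pytest.raises(ValueError, match="rule"):
            construct_volume(stack, rule="simpson")

    def test_error_decreases_with_slice_spacing(self):
        r, h = 2.0, 1.0
        analytic = math.pi * r**2 * h
        errors = []
        for spacing in (400.0, 200.0, 100.0):
            n_slices = int(2 * 2.4 * r * 1e3 / spacing) // 2 + 1
            stack = _disk_bmode_stack(r, h, n_slices=n_slices, slice_spacing_um=spacing)
            est = construct_volume(stack, threshold_db=30.0)
            errors.append(abs(est.volume_mm3 - analytic))
        assert errors[2] <= errors[1] <= errors[0]
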