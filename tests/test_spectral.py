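"""Spectral estimation: closed-form band statistics, regression, attenuation
correction, forward/inverse exactness and recovery oracles on simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import susi.spectral as sp
from susi.spectral import (
    RoiSpec,
    SpectralFit,
    acoustic_concentration_from_mbf,
    calcium_mass,
    concentration_and_impedance,
    correct_attenuation,
    calibrated_spectrum,
    ensemble_fit,
    equivalent_scatterer_number,
    fit_slope_mbf,
    fit_window_table,
    impedance_after_deposition,
    mbf_from_concentration,
    radius_from_slope,
    relative_impedance,
    roi_statistics,
    scatterer_density_from_impedance,
    slope_from_radius,
)

BAND = (22.0, 88.0)


class TestBandStatistics:
    def test_log_mean_matches_quadrature(self):
        f1, f2 = 21.0, 87.0
        numeric = quad(np.log, f1, f2)[0] / (f2 - f1)
        assert math.isclose(sp.band_log_mean(f1, f2), numeric, rel_tol=1e-10)

    def test_log_slope_matches_quadrature(self):
        f1, f2 = 21.0, 87.0
        fc = 0.5 * (f1 + f2)
        num = quad(lambda f: (f - fc) * np.log(f), f1, f2)[0]
        numeric = num / ((f2 - f1) ** 3 / 12.0)
        assert math.isclose(sp.band_log_slope(f1, f2), numeric, rel_tol=1e-10)


class TestFitSlopeMbf:
    def test_exact_line(self):
        freqs = np.linspace(15, 95, 161)
        spectrum = 0.5 * freqs - 10.0
        fit = fit_slope_mbf(spectrum, freqs, BAND)
        fc = 0.5 * (BAND[0] + BAND[1])
        assert math.isclose(fit.slope_raw, 0.5, rel_tol=1e-12)
        assert math.isclose(fit.mbf_raw, 0.5 * fc - 10.0, rel_tol=1e-12)

    def test_flat_spectrum(self):
        freqs = np.linspace(15, 95, 161)
        fit = fit_slope_mbf(np.zeros_like(freqs), freqs, BAND)
        assert abs(fit.slope_raw) < 1e-12 and abs(fit.mbf_raw) < 1e-12

    def test_noisy_line_within_three_standard_errors(self):
        rng = np.random.default_rng(3)
        freqs = np.linspace(15, 95, 161)
        sel = (freqs >= BAND[0]) & (freqs <= BAND[1])
        spectrum = 0.5 * freqs - 10.0 + rng.normal(0, 1.0, freqs.size)
        fit = fit_slope_mbf(spectrum, freqs, BAND)
        se = 1.0 / math.sqrt(np.sum((freqs[sel] - freqs[sel].mean()) ** 2))
        assert abs(fit.slope_raw - 0.5) < 3 * se

    def test_narrow_band_rejected(self):
        freqs = np.linspace(15, 95, 20)
        with pytest.raises(ValueError, match="5 regression points"):
            fit_slope_mbf(np.zeros(20), freqs, (50.0, 55.0))


class TestAttenuationCorrection:
    def test_zero_alpha_identity(self):
        fit = SpectralFit(slope_raw=0.3, mbf_raw=-12.0, analysis_band=BAND, depth_mm=1.0)
        out = correct_attenuation(fit, 0.0)
        assert out.slope == fit.slope_raw and out.mbf == fit.mbf_raw

    def test_hand_computed_case(self):
        # alpha = 0.5 dB/(cm MHz), z = 0.1 cm, f_c = 47.5 MHz
        fit = SpectralFit(slope_raw=0.0, mbf_raw=0.0, analysis_band=(20.0, 75.0))
        out = correct_attenuation(fit, 0.5, z_cm=0.1, f_c=47.5)
        assert math.isclose(out.slope - fit.slope_raw, 0.1, rel_tol=1e-12)
        assert math.isclose(out.mbf - fit.mbf_raw, 4.75, rel_tol=1e-12)

    def test_negative_depth_rejected(self):
        fit = SpectralFit(slope_raw=0.0, mbf_raw=0.0, analysis_band=BAND)
        with pytest.raises(ValueError, match="non-negative"):
            correct_attenuation(fit, 0.5, z_cm=-0.1)


class TestForwardInverseIdentities:
    @pytest.mark.parametrize("radius_um", [3.0, 3.5, 7.0, 12.5])
    def test_radius_round_trip(self, radius_um):
        m = slope_from_radius(radius_um, BAND, n=4.0, c_t=1540.0)
        back = radius_from_slope(m, n=4.0, c_t=1540.0, band=BAND)
        assert math.isclose(back, radius_um, rel_tol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.5, max_value=20.0),
        st.floats(min_value=0.0, max_value=6.0),
        st.floats(min_value=1400.0, max_value=1650.0),
    )
    def test_radius_round_trip_property(self, radius_um, n, c_t):
        m = slope_from_radius(radius_um, BAND, n=n, c_t=c_t)
        assert math.isclose(
            radius_from_slope(m, n=n, c_t=c_t, band=BAND), radius_um, rel_tol=1e-9
        )

    def test_nonphysical_slope_flagged(self):
        system_slope = slope_from_radius(1e-9, BAND)  # zero-radius limit
        assert math.isnan(radius_from_slope(system_slope + 0.1, band=BAND))

    def test_concentration_round_trip(self):
        cq2 = 7.2e5
        mbf = mbf_from_concentration(cq2, 7.0, BAND, shape_parameter_db=-150.0)
        back = acoustic_concentration_from_mbf(mbf, 7.0, shape_parameter_db=-150.0, band=BAND)
        assert math.isclose(back, cq2, rel_tol=1e-12)

    def test_factorization(self):
        c, q = concentration_and_impedance(360.0, known_c=1000.0)
        assert math.isclose(q, 0.6, rel_tol=1e-12)
        c, q = concentration_and_impedance(360.0, known_q=1.0)
        assert math.isclose(c, 360.0, rel_tol=1e-12)
        with pytest.raises(ValueError):
            concentration_and_impedance(360.0)
        with pytest.raises(ValueError):
            concentration_and_impedance(360.0, known_c=1.0, known_q=1.0)

    def test_equivalent_scatterer_number(self):
        assert equivalent_scatterer_number(360.0, 100.0) == pytest.approx(3.6e4)
        assert equivalent_scatterer_number(360.0, 0.0) == 0.0


class TestImpedanceAndCalcium:
    def test_impedance_definition_and_inverse(self):
        q = relative_impedance(1100.0, 1600.0, 1000.0, 1540.0)
        assert math.isclose(q, (1100 * 1600 - 1000 * 1540) / (1000 * 1540), rel_tol=1e-12)
        rho = scatterer_density_from_impedance(q, 1600.0, 1000.0, 1540.0)
        assert math.isclose(rho, 1100.0, rel_tol=1e-12)

    def test_no_deposition_zero_mass(self):
        est = calcium_mass(0.6, 0.6, 1e4, 7.0)
        assert est.calcium_mass_ug == 0.0

    def test_forward_inverse_mass_round_trip(self):
        mass = 4.0  # ug over 1e4 scatterers
        q_i = impedance_after_deposition(0.6, mass, 1e4, 7.0)
        est = calcium_mass(0.6, q_i, 1e4, 7.0)
        assert math.isclose(est.calcium_mass_ug, mass, rel_tol=1e-12)

    def test_impedance_drop_clamped_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            est = calcium_mass(0.6, 0.5, 1e4, 7.0)
        assert est.calcium_mass_ug == 0.0
        assert "zero calcium" in caplog.text

    def test_concentration_per_volume(self):
        est = calcium_mass(0.6, 0.8, 1e4, 7.0, construct_volume_mm3=100.0)
        assert math.isclose(
            est.calcium_concentration_ug_per_ml, est.calcium_mass_ug / 0.1, rel_tol=1e-12
        )


class TestCalibratedSpectra:
    def test_point_scatterers_give_flat_spectrum(self, transducer, medium):
        """With n = 0, a -> 0 and alpha = 0 the calibrated spectrum is white."""
        from susi.bulk import bulk_properties
        from susi.rf import AcquisitionGrid
        from susi.simulate import PhantomConfig, simulate_scan

        cfg = PhantomConfig(
            scatterer_diameter_um=0.5,
            number_concentration=4000.0,
            geometry_parameter=0.0,
            attenuation_coeff=0.0,
            thickness_mm=2.0,
            snr_db=None,
            rng_seed=9,
        )
        grid = AcquisitionGrid(n_lines=120, n_slices=1)
        sample, ref = simulate_scan(cfg, transducer, grid, medium, seed=9)
        props, surfaces = bulk_properties(sample, ref, medium)
        spectra = calibrated_spectrum(sample, ref, surfaces, c_t=props.speed_of_sound)
        mean_db = 10 * np.log10(np.mean(10 ** (spectra.spectra_db / 10.0), axis=0))
        sel = (spectra.freqs_mhz >= spectra.band[0]) & (spectra.freqs_mhz <= spectra.band[1])
        assert np.ptp(mean_db[sel]) < 3.0  # flat within +-1.5 dB
        ens = ensemble_fit(spectra, 0.0, n=0.0, c_t=props.speed_of_sound)
        assert abs(ens["slope"]) < 0.01

    def test_spectrum_matches_gaussian_form_factor(self, cell_analysis):
        """Ensemble calibrated spectrum tracks the closed-form model within
        1 dB (shape) over the -9 dB analysis band."""
        spectra = cell_analysis["spectra"]
        cfg = cell_analysis["config"]
        props = cell_analysis["props"]
        comp = (
            spectra.spectra_db
            + 2 * props.attenuation_coeff * (spectra.depth_mm[:, None] / 10.0) * spectra.freqs_mhz
        )
        mean_db = 10 * np.log10(np.mean(10 ** (comp / 10.0), axis=0))
        f = spectra.freqs_mhz
        model = (
            cell_analysis["e_db"]
            + 10 * np.log10(cfg.number_concentration * cfg.relative_impedance**2 * cfg.radius_um**6)
            + 10 * cfg.geometry_parameter * np.log10(np.where(f > 0, f, 1.0))
            - (10 / math.log(10)) * sp.form_factor_exponent(f, cfg.radius_um, props.speed_of_sound)
        )
        sel = (f >= spectra.band[0]) & (f <= spectra.band[1])
        resid = mean_db[sel] - model[sel]
        assert np.max(np.abs(resid - resid.mean())) < 1.0
        assert abs(resid.mean()) < 1.0  # absolute level via the analytic E

    def test_scaling_sample_shifts_mbf_only(self, cell_analysis):
        """x k on the sample RF: MBF' shifts by 20 log10 k, slope unchanged;
        scaling sample and reference together changes nothing."""
        from susi.rf import RFVolume

        sample = cell_analysis["sample"]
        ref = cell_analysis["reference"]
        surfaces = cell_analysis["surfaces"]
        c_t = cell_analysis["props"].speed_of_sound
        k = 3.7

        def fits(s, r):
            spec = calibrated_spectrum(s, r, surfaces, c_t=c_t)
            fit = fit_slope_mbf(spec.spectra_db[0], spec.freqs_mhz, spec.band)
            return fit

        scaled = RFVolume(k * sample.samples, sample.grid, sample.transducer, "sample")
        scaled_ref = RFVolume(k * ref.samples, ref.grid, ref.transducer, "reference")
        base = fits(sample, ref)
        shifted = fits(scaled, ref)
        both = fits(scaled, scaled_ref)
        assert math.isclose(shifted.mbf_raw - base.mbf_raw, 20 * math.log10(k), abs_tol=1e-9)
        assert math.isclose(shifted.slope_raw, base.slope_raw, abs_tol=1e-9)
        assert math.isclose(both.mbf_raw, base.mbf_raw, abs_tol=1e-9)

    def test_empirical_calibration_matches_analytic_system_constant(
        self, phantom_scan, transducer, medium
    ):
        from susi.bulk import bulk_properties
        from susi.simulate import analytic_shape_parameter
        from susi.spectral import WindowSpec, calibrate_shape_parameter

        cfg, sample, ref = phantom_scan
        props, surfaces = bulk_properties(sample, ref, medium)
        spectra = calibrated_spectrum(sample, ref, surfaces, c_t=props.speed_of_sound)
        e_emp = calibrate_shape_parameter(
            spectra,
            props.attenuation_coeff,
            true_cq2=cfg.number_concentration * cfg.relative_impedance**2,
            true_radius_um=cfg.radius_um,
            c_t=props.speed_of_sound,
        )
        e_ana = analytic_shape_parameter(
            cfg, transducer, medium, WindowSpec(), c_t=props.speed_of_sound
        )
        assert abs(e_emp - e_ana) < 0.5  # dB

    def test_corrected_mbf_has_no_depth_trend(self, phantom_scan, transducer, medium):
        """After 2 alpha z f_c compensation the MBF is depth-independent."""
        from susi.bulk import bulk_properties

        cfg, sample, ref = phantom_scan
        props, surfaces = bulk_properties(sample, ref, medium)
        spectra = calibrated_spectrum(sample, ref, surfaces, c_t=props.speed_of_sound)
        table = fit_window_table(spectra, props.attenuation_coeff, c_t=props.speed_of_sound)
        z = table["z_mm"].to_numpy()
        mbf = table["mbf"].to_numpy()
        slope, intercept = np.polyfit(z, mbf, 1)
        resid = mbf - (slope * z + intercept)
        se = np.std(resid, ddof=2) / math.sqrt(np.sum((z - z.mean()) ** 2))
        assert abs(slope) < 2.5 * se  # consistent with zero at ~95%


class TestRoiStatistics:
    def _table(self, values, lines, slices=None):
        import pandas as pd

        slices = slices if slices is not None else [0] * len(values)
        return pd.DataFrame(
            {
                "slice": slices,
                "line": lines,
                "axial": range(len(values)),
                "diameter_um": values,
                "cq2_mm3": values,
            }
        )

    def test_identical_values(self):
        table = self._table([5.0] * 12, [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 1, 3])
        out = roi_statistics(table, RoiSpec(), lateral_spacing_um=31.0)
        assert len(out) == 1
        assert out["diameter_um_mean"].iloc[0] == 5.0
        assert out["diameter_um_sd"].iloc[0] == 0.0

    def test_default_roi_spans_19_lines(self):
        # 0.6 mm lateral extent over 31 um line spacing -> 19 A-lines per ROI
        table = self._table([1.0] * 40, list(range(40)))
        out = roi_statistics(table, RoiSpec(), lateral_spacing_um=31.0, min_windows=1)
        assert sorted(out["roi_lat"]) == [0, 1, 2]
        counts = table.groupby(table["line"] // 19).size()
        assert counts.loc[0] == 19

    def test_construct_mean_is_size_weighted_roi_mean(self):
        lines = [0] * 6 + [19] * 10
        values = [2.0] * 6 + [5.0] * 10
        table = self._table(values, lines)
        out = roi_statistics(table, RoiSpec(), lateral_spacing_um=31.0)
        weighted = np.average(out["diameter_um_mean"], weights=out["n_windows"])
        assert math.isclose(weighted, np.mean(values), rel_tol=1e-12)

    def test_sparse_rois_excluded(self, caplog):
        table = self._table([1.0, 2.0], [0, 30])
        with caplog.at_level("INFO", logger="susi.spectral"):
            out = roi_statistics(table, RoiSpec(), lateral_spacing_um=31.0, min_windows=5)
        assert out.empty
        assert "excluded" in caplog.text
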