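import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtmfa.nirs import (
    PreprocessConfig,
    SELResult,
    SpectraSet,
    ValidationReport,
    calibrate,
    cross_validate,
    fit_pls,
    interpolate_reference,
    load_calibration,
    preprocess,
    qualify_model,
    read_spectra,
    save_calibration,
    sel,
    select_window,
    split_calibration_validation,
    validate_external,
    write_spectra,
)


def _flat_config(**kw):
    return PreprocessConfig(excluded_bands=(), mean_center=False, **kw)


class TestPreprocess:
    def test_second_derivative_exact_on_quadratic(self):
        wl = np.arange(0.0, 200.0)
        y = wl**2
        out = preprocess(SpectraSet(wl, y[None, :], [0.0]), _flat_config())
        np.testing.assert_allclose(out.absorbance, 2.0, atol=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(coeffs=st.tuples(
        st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)))
    def test_exact_on_any_quadratic(self, coeffs):
        a, b, c = coeffs
        wl = np.arange(0.0, 120.0)
        y = a * wl**2 + b * wl + c
        out = preprocess(SpectraSet(wl, y[None, :], [0.0]), _flat_config())
        np.testing.assert_allclose(out.absorbance, 2 * a, atol=1e-8)

    def test_constant_spectrum_derivative_is_zero(self):
        wl = np.arange(0.0, 100.0)
        out = preprocess(SpectraSet(wl, np.full((3, 100), 7.0), [0, 1, 2]),
                         _flat_config())
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_mean_centering_zeroes_column_means(self):
        rng = np.random.default_rng(0)
        wl = np.arange(800.0, 2200.0, 2.0)
        spec = SpectraSet(wl, rng.normal(size=(20, len(wl))), np.arange(20.0))
        out = preprocess(spec, PreprocessConfig())
        np.testing.assert_allclose(out.absorbance.mean(axis=0), 0.0, atol=1e-12)

    def test_excluded_bands_removed_and_segments_independent(self):
        wl = np.arange(800.0, 2200.0, 2.0)
        spec = SpectraSet(wl, np.zeros((1, len(wl))), [0.0])
        out = preprocess(spec, PreprocessConfig())
        assert not np.any((out.wavelengths >= 1380) & (out.wavelengths <= 1420))
        assert not np.any(out.wavelengths > 2000)

    def test_segment_shorter_than_window_is_named(self):
        wl = np.arange(800.0, 900.0, 2.0)  # 50 channels
        spec = SpectraSet(wl, np.zeros((1, len(wl))), [0.0])
        cfg = PreprocessConfig(excluded_bands=((850.0, 860.0),))
        with pytest.raises(ValueError, match="segment"):
            preprocess(spec, cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=32)
        with pytest.raises(ValueError):
            PreprocessConfig(sg_polyorder=1, sg_derivative=2)


class TestSelectWindow:
    def test_channel_count_on_2nm_grid(self):
        wl = np.arange(800.0, 2200.0 + 1, 2.0)
        spec = SpectraSet(wl, np.zeros((1, len(wl))), [0.0])
        sub = select_window(spec, (1250.0, 1350.0))
        assert len(sub.wavelengths) == 51

    def test_full_window_is_identity(self):
        wl = np.arange(800.0, 2200.0 + 1, 2.0)
        spec = SpectraSet(wl, np.zeros((2, len(wl))), [0.0, 1.0])
        sub = select_window(spec, (0.0, 1e5))
        np.testing.assert_array_equal(sub.wavelengths, wl)

    def test_window_outside_grid_rejected(self):
        wl = np.arange(800.0, 2200.0, 2.0)
        spec = SpectraSet(wl, np.zeros((1, len(wl))), [0.0])
        with pytest.raises(ValueError):
            select_window(spec, (3000.0, 3100.0))


class TestInterpolateReference:
    def test_exact_at_reference_times(self):
        vals, kept = interpolate_reference([0.0, 2.0], [10.0, 20.0], [0.0, 2.0])
        np.testing.assert_allclose(vals, [10.0, 20.0])

    def test_midpoint(self):
        vals, _ = interpolate_reference([0.0, 2.0], [10.0, 20.0], [1.0])
        assert vals[0] == pytest.approx(15.0)

    def test_out_of_range_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            vals, kept = interpolate_reference([0.0, 4.0], [1.0, 2.0], [2.0, 5.0])
        assert len(vals) == 1 and not kept[1]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            interpolate_reference([2.0, 0.0], [1.0, 2.0], [1.0])


class TestSplit:
    def test_study_sizes(self):
        cal, val = split_calibration_validation(115, 30, seed=1)
        assert len(cal) == 85 and len(val) == 30
        assert len(np.intersect1d(cal, val)) == 0
        assert len(np.union1d(cal, val)) == 115

    def test_reproducible(self):
        assert np.array_equal(split_calibration_validation(50, 10, 3)[0],
                              split_calibration_validation(50, 10, 3)[0])

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_calibration_validation(30, 30, 1)


class TestFitPLS:
    def test_rank_one_signal_single_component(self):
        rng = np.random.default_rng(1)
        X = np.zeros((20, 30))
        X[:, 7] = rng.normal(size=20)
        y = 3.0 * X[:, 7]
        coef, x_mean, y_mean = fit_pls(X, y, 1)
        yhat = (X - x_mean) @ coef + y_mean
        assert np.sqrt(np.mean((y - yhat) ** 2)) < 1e-8

    def test_two_component_mixture_matches_least_squares_oracle(self):
        """Noiseless two-analyte Beer-Lambert mixtures: PLS with 2 latent
        variables reproduces the regression implied by the pure spectra."""
        rng = np.random.default_rng(2)
        s1, s2 = rng.normal(size=30), rng.normal(size=30)
        c1, c2 = rng.uniform(0, 40, 25), rng.uniform(0, 30, 25)
        X = np.outer(c1, s1) + np.outer(c2, s2)
        coef, x_mean, y_mean = fit_pls(X, c1, 2)
        yhat = (X - x_mean) @ coef + y_mean
        assert np.max(np.abs(yhat - c1)) < 1e-6
        # oracle: ordinary least squares on the 2-dimensional column space
        basis = np.vstack([s1, s2]).T
        scores = X @ np.linalg.pinv(basis).T
        beta, *_ = np.linalg.lstsq(
            np.column_stack([scores, np.ones(25)]), c1, rcond=None)
        oracle = np.column_stack([scores, np.ones(25)]) @ beta
        np.testing.assert_allclose(yhat, oracle, atol=1e-6)

    def test_orthogonal_target_gives_no_fit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)  # independent of X
        coef, x_mean, y_mean = fit_pls(X, y, 1)
        yhat = (X - x_mean) @ coef + y_mean
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot < 0.3

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(np.zeros((5, 3)), np.zeros(5), 10)


class TestCrossValidate:
    def test_noiseless_linear_loo(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 8))
        y = X @ rng.normal(size=8)
        rmsecv, r2 = cross_validate(X, y, 8)
        assert rmsecv < 1e-6 and r2 > 1 - 1e-9

    def test_overfitting_elbow_exists(self):
        """On noisy two-factor data RMSECV improves to the true rank then
        degrades as components fit noise."""
        rng = np.random.default_rng(42)
        T = rng.normal(size=(40, 2))
        X = T @ rng.normal(size=(2, 60)) + rng.normal(0, 0.5, (40, 60))
        y = T @ np.array([1.0, -0.5]) + rng.normal(0, 0.3, 40)
        curve = [cross_validate(X, y, k)[0] for k in range(1, 9)]
        k_best = int(np.argmin(curve))
        assert curve[k_best] < curve[0]
        assert curve[-1] > curve[k_best]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.zeros((1, 3)), np.zeros(1), 1)


class TestValidationReport:
    @pytest.mark.parametrize("rmsep,rmsecv,expected", [
        (2.90, 3.38, 0.86),   # glycerol-model arithmetic
        (1.17, 0.93, 1.26),   # biomass-model arithmetic
    ])
    def test_rmsep_rmsecv_ratio(self, rmsep, rmsecv, expected):
        rep = ValidationReport(analyte="x", rmsec=0.0, r2_cal=1.0,
                               rmsecv=rmsecv, rmsep=rmsep)
        assert round(rep.rmsep_rmsecv_ratio, 2) == expected

    def test_perfect_predictions(self):
        class Dummy:
            coef = np.array([1.0])
            x_mean = np.array([0.0])
            y_mean = 0.0
            analyte = "x"
            report = None

        y = np.array([1.0, 2.0, 3.0])
        rep = validate_external(Dummy(), y[:, None], y)
        assert rep.rmsep == pytest.approx(0.0, abs=1e-12)
        assert rep.r2_ext == pytest.approx(1.0)

    def test_empty_validation_rejected(self):
        class Dummy:
            coef = np.array([1.0]); x_mean = np.array([0.0]); y_mean = 0.0
            analyte = "x"; report = None

        with pytest.raises(ValueError):
            validate_external(Dummy(), np.zeros((0, 1)), np.zeros(0))


class TestSEL:
    def test_identical_replicates(self):
        assert sel(np.ones((4, 2))).sel == 0.0

    def test_hand_example(self):
        table = np.array([[1.0, 1.2], [2.0, 1.8]])
        assert sel(table).sel == pytest.approx(np.sqrt(0.02), rel=1e-12)

    def test_recovers_noise_sd_in_simulation(self):
        """Duplicate assays of 16 samples: the pooled SEL converges on the
        assay noise sd."""
        rng = np.random.default_rng(8)
        sigma = 0.79
        sels = []
        for _ in range(1000):
            truth = rng.uniform(0, 30, 16)
            table = truth[:, None] + rng.normal(0, sigma, (16, 2))
            sels.append(sel(table).sel)
        assert np.mean(sels) == pytest.approx(sigma, rel=0.05)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            sel(np.ones((4, 1)))


class TestQualifyModel:
    def _report(self, r2, rmsep):
        return ValidationReport(analyte="x", rmsec=0.0, r2_cal=1.0,
                                rmsecv=1.0, rmsep=rmsep, r2_ext=r2)

    def test_glycerol_style_model_is_excellent(self):
        verdict = qualify_model(self._report(0.95, 2.90),
                                SELResult(2.37, 2.20, 16, 2))
        assert verdict == "excellent"

    def test_biomass_style_model_is_excellent(self):
        verdict = qualify_model(self._report(0.94, 1.17),
                                SELResult(0.79, 0.56, 16, 2))
        assert verdict == "excellent"

    def test_low_r2_is_qualitative_only(self):
        verdict = qualify_model(self._report(0.5, 0.1),
                                SELResult(1.0, 1.0, 16, 2))
        assert verdict == "qualitative-only"

    def test_zero_sel_falls_back_to_r2(self):
        with pytest.warns(UserWarning, match="SEL is zero"):
            verdict = qualify_model(self._report(0.95, 1.0),
                                    SELResult(0.0, 0.0, 16, 2))
        assert verdict == "excellent"


class TestEndToEnd:
    def test_both_analytes_qualify_on_synthetic_run(self, calibrations):
        for name, model in calibrations.items():
            assert model.report.r2_ext > 0.90, name

    def test_water_band_drift_does_not_change_predictions(self, calibrations,
                                                          spectra):
        model = calibrations["biomass"]
        perturbed = SpectraSet(
            spectra.wavelengths,
            spectra.absorbance
            + 0.5 * ((spectra.wavelengths >= 1385) & (spectra.wavelengths <= 1415)),
            spectra.times,
        )
        np.testing.assert_allclose(model.predict(perturbed),
                                   model.predict(spectra), atol=1e-9)

    def test_rmsec_not_above_rmsecv_typically(self):
        """Training error should rarely exceed cross-validated error."""
        rng = np.random.default_rng(9)
        violations = 0
        for _ in range(200):
            T = rng.normal(size=(25, 2))
            X = T @ rng.normal(size=(2, 20)) + rng.normal(0, 0.3, (25, 20))
            y = T[:, 0] + rng.normal(0, 0.3, 25)
            coef, x_mean, y_mean = fit_pls(X, y, 2)
            rmsec = np.sqrt(np.mean((y - ((X - x_mean) @ coef + y_mean)) ** 2))
            rmsecv, _ = cross_validate(X, y, 2)
            violations += rmsec > rmsecv
        assert violations / 200 < 0.10

    def test_model_persistence_round_trip(self, calibrations, spectra, tmp_path):
        model = calibrations["glycerol"]
        path = tmp_path / "model.json"
        save_calibration(model, path)
        back = load_calibration(path)
        np.testing.assert_allclose(back.predict(spectra), model.predict(spectra))

    def test_grid_mismatch_rejected(self, calibrations):
        model = calibrations["biomass"]
        wl = np.arange(900.0, 1900.0, 2.0)
        other = SpectraSet(wl, np.zeros((1, len(wl))), [0.0])
        with pytest.raises(ValueError, match="grid"):
            model.predict(other)


def test_spectra_csv_round_trip(tmp_path, spectra):
    sub = spectra.subset(np.arange(5))
    path = tmp_path / "spectra.csv"
    write_spectra(sub, path)
    back = read_spectra(path)
    np.testing.assert_allclose(back.absorbance, sub.absorbance, rtol=1e-12)
    np.testing.assert_allclose(back.wavelengths, sub.wavelengths)
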