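"""A1 template, λmax fitting, bootstrap CIs, difference spectra, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimeye import pigment_spectra as ps
from dimeye import synthetic_data as sd
from dimeye.exceptions import (BoundaryWarning, DomainError, FitError,
                               GridMismatchError, NoCrossingError)


class TestTemplate:
    @pytest.mark.parametrize("wl, lmax, expected, tol", [
        (547, 547, 1.00, 0.005),    # unity at the peak
        (650, 547, 0.041, 0.001),   # long-wavelength shoulder
        (361, 547, 0.26, 0.01),     # beta band dominates in the UV
    ])
    def test_published_constant_evaluation(self, wl, lmax, expected, tol):
        assert ps.template_a1(wl, lmax) == pytest.approx(expected, abs=tol)

    def test_beta_band_flag(self):
        with_beta = ps.template_a1(361, 547, include_beta=True)
        without = ps.template_a1(361, 547, include_beta=False)
        assert with_beta - without == pytest.approx(0.26, abs=0.01)

    @pytest.mark.parametrize("lmax", [299, 701])
    def test_lambda_max_range(self, lmax):
        with pytest.raises(DomainError):
            ps.template_a1(500, lmax)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(lmax=st.floats(350, 650))
    def test_peak_value_and_positivity(self, lmax):
        wl = np.arange(300.0, 701.0)
        values = ps.template_a1(wl, lmax)
        assert np.all(values > 0)
        assert ps.template_a1(lmax, lmax) == pytest.approx(1.0, abs=0.01)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(lmax=st.floats(350, 650))
    def test_strictly_decreasing_beyond_peak(self, lmax):
        wl = np.arange(lmax + 10, 801.0, 1.0)
        values = ps.template_a1(wl, lmax)
        assert np.all(np.diff(values) < 0)


class TestFitLambdaMax:
    def test_noiseless_exact_recovery(self, template_spectrum):
        fit = ps.fit_lambda_max(template_spectrum(427))
        assert fit.lambda_max_nm == pytest.approx(427.0, abs=0.1)
        # amplitude compensates the unit-max normalisation: the template's
        # own maximum slightly exceeds 1 where the beta band contributes
        assert fit.amplitude == pytest.approx(1.0, abs=5e-3)
        assert fit.rss < 1e-10

    def test_matches_exhaustive_grid_oracle(self):
        spectrum = sd.make_spectrum(547, noise_sd=0.01, seed=3)
        fit = ps.fit_lambda_max(spectrum)
        # independent oracle: exhaustive 0.01-nm scan with closed-form amplitude
        wl = spectrum.wavelength_nm
        y = spectrum.absorbance / spectrum.absorbance.max()
        candidates = np.arange(540.0, 554.0, 0.01)
        rss = np.empty_like(candidates)
        for i, lm in enumerate(candidates):
            t = ps.template_a1(wl, lm)
            amp = (t @ y) / (t @ t)
            rss[i] = np.sum((y - amp * t) ** 2)
        oracle = candidates[np.argmin(rss)]
        assert abs(fit.lambda_max_nm - oracle) <= 0.05

    @pytest.mark.parametrize("lmax", [360, 427, 547, 555])
    def test_parameter_recovery_mean_error(self, lmax):
        estimates = [
            ps.fit_lambda_max(sd.make_spectrum(lmax, noise_sd=0.01, seed=s)
                              ).lambda_max_nm
            for s in range(50)]
        assert np.mean(np.abs(np.array(estimates) - lmax)) < 1.0

    def test_lw_duplicate_red_shift_preserved(self):
        # duplicated LW pigments 8 nm apart must stay 8 +- 1 nm apart
        lw1 = [ps.fit_lambda_max(sd.make_spectrum(547, noise_sd=0.01, seed=s)
                                 ).lambda_max_nm for s in range(30)]
        lw2 = [ps.fit_lambda_max(sd.make_spectrum(555, noise_sd=0.01, seed=s)
                                 ).lambda_max_nm for s in range(30)]
        assert np.mean(lw2) - np.mean(lw1) == pytest.approx(8.0, abs=1.0)

    def test_constant_spectrum_fails(self):
        wl = np.arange(300.0, 701.0)
        flat = ps.Spectrum(wl, np.ones_like(wl), condition="synthetic")
        with pytest.raises(FitError):
            ps.fit_lambda_max(flat)

    def test_optimum_at_bound_warns(self, template_spectrum):
        # peak outside the allowed range: optimum pinned to the upper bound
        with pytest.warns(BoundaryWarning):
            fit = ps.fit_lambda_max(template_spectrum(547),
                                    bounds_nm=(300, 500))
        assert fit.lambda_max_nm == 500.0

    def test_baseline_absorbs_offset(self):
        spectrum = sd.make_spectrum(547, noise_sd=0.0, baseline=0.2, seed=0)
        fit = ps.fit_lambda_max(spectrum, baseline=True)
        assert fit.lambda_max_nm == pytest.approx(547.0, abs=0.2)
        assert fit.baseline > 0.1


class TestBootstrapCI:
    def test_deterministic_under_seed(self):
        spectrum = sd.make_spectrum(547, noise_sd=0.01, seed=1)
        ci1 = ps.bootstrap_ci(spectrum, 500, seed=42)
        ci2 = ps.bootstrap_ci(spectrum, 500, seed=42)
        assert ci1 == ci2

    def test_noiseless_degenerate_ci(self, template_spectrum):
        spectrum = template_spectrum(547)
        fit = ps.fit_lambda_max(spectrum)
        lo, hi = ps.bootstrap_ci(spectrum, 200, seed=7)
        assert hi - lo < 0.5
        assert lo - 0.25 <= fit.lambda_max_nm <= hi + 0.25

    def test_ci_width_grows_with_noise(self):
        widths = []
        for noise in (0.01, 0.05):
            spectrum = sd.make_spectrum(547, noise_sd=noise, seed=5)
            lo, hi = ps.bootstrap_ci(spectrum, 500, seed=9)
            widths.append(hi - lo)
        assert widths[0] < widths[1]

    def test_fit_with_ci_brackets_point_estimate(self):
        spectrum = sd.make_spectrum(427, noise_sd=0.02, seed=2)
        result = ps.fit_with_ci(spectrum, 500, seed=11)
        lo, hi = result.ci_95
        assert lo <= result.lambda_max_nm <= hi
        assert result.n_boot == 500 and result.seed == 11


class TestDifferenceSpectrum:
    def test_self_difference_is_zero(self, template_spectrum):
        spectrum = template_spectrum(427)
        diff = ps.difference_spectrum(spectrum, spectrum)
        assert np.all(diff.absorbance == 0)
        assert diff.condition == "difference"

    def test_antisymmetry(self, template_spectrum):
        a, b = template_spectrum(427), template_spectrum(547)
        ab = ps.difference_spectrum(a, b)
        ba = ps.difference_spectrum(b, a)
        assert np.allclose(ab.absorbance, -ba.absorbance)

    def test_uv_minus_photoproduct_sign_pattern(self, template_spectrum):
        # dark pigment at 362, acid photoproduct band at 436: the
        # difference must be positive near 362 and negative near 436
        wl = np.arange(300.0, 701.0)
        dark = template_spectrum(362)
        acid = ps.Spectrum(wl, ps.template_a1(wl, 436), condition="synthetic")
        diff = ps.difference_spectrum(dark, acid)
        near = lambda target: np.argmin(np.abs(wl - target))
        assert diff.absorbance[near(362)] > 0
        assert diff.absorbance[near(460)] < 0

    def test_grid_mismatch_rejected(self):
        a = ps.Spectrum(np.arange(300.0, 701.0), np.ones(401) * 0.5)
        b = ps.Spectrum(np.arange(300.0, 700.0, 2.0), np.ones(200) * 0.5)
        with pytest.raises(GridMismatchError):
            ps.difference_spectrum(a, b)

    def test_interpolation_on_overlap(self):
        a = ps.Spectrum(np.arange(300.0, 701.0), np.ones(401) * 0.5)
        b = ps.Spectrum(np.arange(350.0, 751.0, 2.0), np.ones(201) * 0.2)
        diff = ps.difference_spectrum(a, b, interpolate=True)
        assert diff.wavelength_nm[0] == 350.0
        assert diff.wavelength_nm[-1] == 700.0
        assert np.allclose(diff.absorbance, 0.3)

    def test_disjoint_ranges_rejected(self):
        a = ps.Spectrum(np.arange(300.0, 401.0), np.ones(101) * 0.5)
        b = ps.Spectrum(np.arange(500.0, 601.0), np.ones(101) * 0.5)
        with pytest.raises(GridMismatchError):
            ps.difference_spectrum(a, b, interpolate=True)


class TestContaminationWorkflow:
    """Free retinal absorbs near 380 nm and biases direct UV-pigment fits;
    the dark-minus-acid difference cancels it."""

    def _acid_spectrum(self, wl, seed):
        # denatured pigment: protonated photoproduct band at 436 nm plus
        # the unchanged free-retinal contamination
        rng = np.random.default_rng(seed)
        y = (0.9 * np.exp(-0.5 * ((wl - 436.0) / 20.0) ** 2)
             + 0.3 * np.exp(-0.5 * ((wl - 380.0) / 30.0) ** 2)
             + rng.normal(0, 0.02, wl.shape))
        return ps.Spectrum(wl, y, condition="synthetic")

    def test_direct_fit_biased_toward_contaminant(self):
        biases = []
        for seed in range(100, 105):
            dark = sd.make_spectrum(362, noise_sd=0.02,
                                    contamination_amplitude=0.3, seed=seed)
            biases.append(ps.fit_lambda_max(dark).lambda_max_nm - 362)
        assert np.mean(biases) > 3.0    # pulled toward 380

    def test_difference_workflow_removes_bias(self):
        biases = []
        for seed in range(100, 105):
            dark = sd.make_spectrum(362, noise_sd=0.02,
                                    contamination_amplitude=0.3, seed=seed)
            acid = self._acid_spectrum(dark.wavelength_nm, seed + 1000)
            diff = ps.difference_spectrum(dark, acid)
            fit = ps.fit_lambda_max(diff, fit_window_nm=(300, 400))
            biases.append(fit.lambda_max_nm - 362)
        assert abs(np.mean(biases)) < 2.0


class TestPeakAndOxime:
    def test_template_peak(self, template_spectrum):
        assert ps.peak_wavelength(template_spectrum(427)) == \
            pytest.approx(427, abs=1)

    def test_synthetic_oxime_peak(self):
        wl = np.arange(300.0, 701.0)
        rng = np.random.default_rng(3)
        y = np.exp(-0.5 * ((wl - 360.0) / 30.0) ** 2) + rng.normal(0, 0.01,
                                                                   wl.shape)
        spectrum = ps.Spectrum(wl, y, condition="synthetic")
        assert ps.peak_wavelength(spectrum, smoothing_window_nm=10) == \
            pytest.approx(360, abs=3)

    def test_monotone_spectrum_boundary_warning(self):
        wl = np.arange(300.0, 701.0)
        spectrum = ps.Spectrum(wl, np.linspace(0, 1, len(wl)))
        with pytest.warns(BoundaryWarning):
            ps.peak_wavelength(spectrum)

    @pytest.mark.parametrize("peak_after, expected", [
        (358, True),     # blue-shift into the oxime band
        (427, False),    # unchanged
        (500, False),    # red-shift, not oxime
    ])
    def test_oxime_shift_detection(self, template_spectrum, peak_after,
                                   expected):
        wl = np.arange(300.0, 701.0)
        before = template_spectrum(427)
        after = ps.Spectrum(wl, np.exp(-0.5 * ((wl - peak_after) / 30.0) ** 2),
                            condition="hydroxylamine_illuminated")
        report = ps.oxime_check(before, after)
        assert report["shifted"] is expected
        assert report["peak_before_nm"] == pytest.approx(427, abs=1)


class TestThresholdWavelength:
    def test_green_pigment_long_shoulder(self):
        wl = ps.threshold_wavelength(547, 0.05, "long")
        assert 640 < wl <= 650     # perceivable out to ~650 nm

    def test_hawkmoth_green_comparison(self):
        wl = ps.threshold_wavelength(525, 0.05, "long")
        assert wl == pytest.approx(620, abs=5)

    def test_level_near_one_returns_peak(self):
        # as the level approaches the peak value the crossing collapses
        # onto the peak (the template is flat to ~0.1% over a few nm there)
        assert ps.threshold_wavelength(547, 0.999, "long") == \
            pytest.approx(547, abs=3)

    def test_bisection_consistency(self):
        # the returned wavelength must evaluate back to the level
        for lmax, level in [(547, 0.05), (427, 0.1), (360, 0.05)]:
            wl = ps.threshold_wavelength(lmax, level, "long")
            assert ps.template_a1(wl, lmax) == pytest.approx(level, abs=1e-3)

    def test_short_limb_crossing(self):
        wl = ps.threshold_wavelength(547, 0.5, "short")
        assert wl < 547
        assert ps.template_a1(wl, 547) == pytest.approx(0.5, abs=1e-3)

    def test_unattainable_level(self):
        # the beta band keeps the template above 5% across 300-λmax
        with pytest.raises(NoCrossingError):
            ps.threshold_wavelength(547, 0.05, "short")

    def test_invalid_level(self):
        with pytest.raises(DomainError):
            ps.threshold_wavelength(547, 1.5)
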