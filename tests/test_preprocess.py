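"""Preprocessing chain: excision, baseline, segmentation, binning, EMSC, SG."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import fibrospec as fs
from fibrospec.preprocess import (
    ALT_DERIV_PRESET,
    _lower_hull_indices,
    bin_image_spatial,
    savgol_matrix,
)
from fibrospec.spectra import CELL, BACKGROUND


def brute_force_lower_hull_baseline(x, y):
    """O(n^2) oracle: greedy minimal-slope walk along the lower hull."""
    i = 0
    support = [0]
    while i < len(x) - 1:
        slopes = (y[i + 1 :] - y[i]) / (x[i + 1 :] - x[i])
        j = i + 1 + int(np.argmin(slopes))
        support.append(j)
        i = j
    return np.interp(x, x[support], y[support])


class TestExcision:
    def test_point_counting_and_gap(self, uniform_axis):
        s = fs.Spectrum(uniform_axis, np.ones(len(uniform_axis)))
        cut = fs.excise_region(s, 2000, 2700)
        v = cut.axis.values
        assert not np.any((v >= 2000) & (v <= 2700))
        removed = np.sum((uniform_axis.values >= 2000) & (uniform_axis.values <= 2700))
        assert len(cut.axis) == len(uniform_axis) - removed
        assert len(cut.axis.segments) == 2

    def test_interval_outside_axis_is_identity(self, uniform_axis):
        s = fs.Spectrum(uniform_axis, np.ones(len(uniform_axis)))
        assert fs.excise_region(s, 5000, 6000) is s

    def test_too_little_left_errors(self):
        axis = fs.WavenumberAxis(np.arange(1000.0, 1100.0, 5.0))
        s = fs.Spectrum(axis, np.ones(len(axis)))
        with pytest.raises(fs.SpectraError, match=">= 8"):
            fs.excise_region(s, 1010, 1090)

    def test_derivative_windows_never_bridge_the_gap(self, uniform_axis, rng):
        """SG after excision equals SG run on each retained segment alone."""
        y = rng.normal(size=len(uniform_axis))
        cut = fs.excise_region(fs.Spectrum(uniform_axis, y), 2000, 2700)
        d = fs.savgol(cut, 7, 2, 2)
        parts = []
        for sl in cut.axis.segment_slices():
            seg = fs.Spectrum(fs.WavenumberAxis(cut.axis.values[sl]), cut.intensity[sl])
            parts.append(fs.savgol(seg, 7, 2, 2).intensity)
        assert np.allclose(d.intensity, np.concatenate(parts), atol=1e-12)


class TestRubberband:
    def test_affine_spectrum_corrects_to_zero(self, uniform_axis):
        y = 0.002 * uniform_axis.values + 1.0
        base, corr = fs.rubberband_baseline(fs.Spectrum(uniform_axis, y))
        assert np.allclose(base.intensity, y, atol=1e-9)
        assert np.allclose(corr.intensity, 0.0, atol=1e-9)

    def test_single_gaussian_with_flat_tails_is_preserved(self, uniform_axis):
        y = np.exp(-0.5 * ((uniform_axis.values - 2200) / 60) ** 2)
        base, corr = fs.rubberband_baseline(fs.Spectrum(uniform_axis, y))
        assert np.max(np.abs(base.intensity)) < 5e-3
        assert np.allclose(corr.intensity, y, atol=5e-3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(hst.integers(0, 2**31 - 1), hst.integers(10, 200))
    def test_matches_brute_force_hull_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(1000, 3000, n))
        x = np.unique(x)
        if x.size < 3:
            return
        y = rng.normal(size=x.size).cumsum()
        base, corr = fs.rubberband_baseline(fs.Spectrum(fs.WavenumberAxis(x), np.abs(y) + 0.1))
        oracle = brute_force_lower_hull_baseline(x, np.abs(y) + 0.1)
        assert np.allclose(base.intensity, oracle, atol=1e-9)
        assert corr.intensity.min() >= 0
        # at least the two endpoints are exact support zeros
        assert corr.intensity[0] == 0 and corr.intensity[-1] == 0
        assert np.sum(np.isclose(corr.intensity, 0, atol=1e-12)) >= 2


class TestSegmentation:
    def test_recovers_truth_mask_on_contrasty_image(self, quiet_config):
        cfg = fs.SyntheticCohortConfig(**{**quiet_config.__dict__, "noise_sd": 0.001})
        img, truth = fs.generate_cell_image(cfg, "CTRL", 17)
        mask = fs.segment_pixels(img, k=2, seed=0)
        assert np.array_equal(mask, truth.mask)

    def test_k1_labels_everything_cell(self, quiet_config):
        img, _ = fs.generate_cell_image(quiet_config, "CTRL", 3)
        assert np.all(fs.segment_pixels(img, k=1) == CELL)

    def test_permutation_equivariance(self, quiet_config, rng):
        cfg = fs.SyntheticCohortConfig(**{**quiet_config.__dict__, "noise_sd": 0.002})
        img, _ = fs.generate_cell_image(cfg, "MS", 29)
        mask = fs.segment_pixels(img, k=2, seed=0)
        perm = rng.permutation(img.n_pixels)
        # permuted pixel order, same spectra: 1-row image with permuted cube
        img_p = fs.SpectralImage(1, img.n_pixels, img.axis, img.cube[perm])
        mask_p = fs.segment_pixels(img_p, k=2, seed=0)
        assert np.array_equal(mask_p, mask[perm])

    def test_identical_pixels_warn_and_label_cell(self, uniform_axis):
        cube = np.ones((16, len(uniform_axis)))
        img = fs.SpectralImage(4, 4, uniform_axis, cube)
        with pytest.warns(UserWarning, match="identical"):
            mask = fs.segment_pixels(img, k=2)
        assert np.all(mask == CELL)


class TestBinning:
    def test_factor_one_is_identity_and_constants_stay_constant(self, uniform_axis):
        s = fs.Spectrum(uniform_axis, np.full(len(uniform_axis), 3.5))
        assert fs.bin_spectra(s, 1) is s
        b = fs.bin_spectra(s, 4)
        assert np.allclose(b.intensity, 3.5, atol=1e-14)

    def test_hand_computed_means(self):
        axis = fs.WavenumberAxis([1000.0, 1004, 1008, 1012])
        s = fs.Spectrum(axis, [1.0, 3, 5, 7])
        b = fs.bin_spectra(s, 2)
        assert np.array_equal(b.axis.values, [1002, 1010])
        assert np.array_equal(b.intensity, [2, 6])

    def test_remainder_kept_as_smaller_bin(self):
        axis = fs.WavenumberAxis([1000.0, 1004, 1008, 1012, 1016])
        b = fs.bin_spectra(fs.Spectrum(axis, [1.0, 3, 5, 7, 9]), 2)
        assert np.array_equal(b.axis.values, [1002, 1010, 1016])
        assert np.array_equal(b.intensity, [2, 6, 9])

    def test_factor_exceeding_axis_errors(self):
        axis = fs.WavenumberAxis([1000.0, 1004, 1008])
        with pytest.raises(fs.SpectraError):
            fs.bin_spectra(fs.Spectrum(axis, [1.0, 2, 3]), 10)

    def test_spatial_binning_averages_cell_pixels_only(self, uniform_axis):
        n = len(uniform_axis)
        cube = np.zeros((4, n))
        cube[0] = 1.0  # the only cell pixel in the 2x2 block
        mask = np.array([CELL, BACKGROUND, BACKGROUND, BACKGROUND], dtype=object)
        img = fs.SpectralImage(2, 2, uniform_axis, cube, mask)
        binned = bin_image_spatial(img, 2)
        assert binned.n_pixels == 1
        assert binned.mask[0] == CELL
        assert np.allclose(binned.cube[0], 1.0)


class TestMieBasisAndEMSC:
    def test_basis_orthonormal(self, uniform_axis):
        basis = fs.build_mie_basis(uniform_axis, n_components=7)
        gram = basis @ basis.T
        assert np.allclose(gram, np.eye(7), atol=1e-8)

    def test_single_curve_grid_returns_normalized_curve(self, uniform_axis):
        basis = fs.build_mie_basis(
            uniform_axis, (4.0, 4.0), (1.3, 1.3), n_components=1, n_radii=1, n_refidx=1
        )
        assert basis.shape == (1, len(uniform_axis))
        assert np.linalg.norm(basis) == pytest.approx(1.0)

    def test_reconstruction_error_decreases_with_components(self, uniform_axis):
        # held-out extinction curves off the training grid
        from fibrospec.preprocess import _van_de_hulst_q

        curves = []
        for r in (2.7, 5.1, 7.3):
            for m in (1.17, 1.31, 1.44):
                rho = 4 * np.pi * r * 1e-4 * (m - 1) * uniform_axis.values
                curves.append(_van_de_hulst_q(rho))
        curves = np.asarray(curves)
        errors = []
        for k in (1, 3, 5, 7):
            basis = fs.build_mie_basis(uniform_axis, n_components=k)
            resid = curves - (curves - curves.mean(0)) @ basis.T @ basis - curves.mean(0)
            errors.append(np.linalg.norm(resid))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_identity_and_exact_linear_model(self, uniform_axis):
        ref = fs.generate_reference_spectrum(uniform_axis)
        corrected, info = fs.scatter_correct(
            ref.intensity[None, :], uniform_axis, ref,
            fs.ScatterParams(mode="emsc_poly"),
        )
        assert np.allclose(corrected[0], ref.intensity, atol=1e-9)
        assert info["a"][0] == pytest.approx(1.0, abs=1e-9)

        s = 2.0 * ref.intensity + 0.1
        corrected, info = fs.scatter_correct(
            s[None, :], uniform_axis, ref, fs.ScatterParams(mode="emsc_poly")
        )
        assert info["a"][0] == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(corrected[0], ref.intensity, atol=1e-9)

    def test_ripple_removed_when_basis_spans_it(self, uniform_axis, rng):
        ref = fs.generate_reference_spectrum(uniform_axis)
        ripple = 0.05 * np.sin(
            2 * np.pi * uniform_axis.values / fs.SyntheticCohortConfig().mie_period + 0.7
        )
        s = ref.intensity + ripple
        corrected, _ = fs.scatter_correct(s[None, :], uniform_axis, ref)
        r = np.corrcoef(corrected[0], ref.intensity)[0, 1]
        assert r >= 0.99

    def test_idempotent_in_poly_mode(self, uniform_axis, rng):
        ref = fs.generate_reference_spectrum(uniform_axis)
        s = 1.7 * ref.intensity + 0.05 + rng.normal(0, 0.01, len(uniform_axis))
        params = fs.ScatterParams(mode="emsc_poly", n_clusters=1)
        once, _ = fs.scatter_correct(s[None, :], uniform_axis, ref, params)
        twice, info = fs.scatter_correct(once, uniform_axis, ref, params)
        assert info["a"][0] == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(twice, once, atol=1e-8)

    def test_tiny_reference_coefficient_flagged(self, uniform_axis):
        ref = fs.generate_reference_spectrum(uniform_axis)
        s = np.zeros((1, len(uniform_axis)))
        with pytest.warns(UserWarning, match="uncorrectable"):
            corrected, info = fs.scatter_correct(
                s, uniform_axis, ref, fs.ScatterParams(mode="emsc_poly")
            )
        assert info["uncorrectable"][0]
        assert np.array_equal(corrected[0], s[0])


class TestSavgol:
    def test_constant_second_derivative_is_zero(self, uniform_axis):
        s = fs.Spectrum(uniform_axis, np.full(len(uniform_axis), 2.0))
        assert np.allclose(fs.savgol(s, 7, 2, 2).intensity, 0.0, atol=1e-12)

    def test_exact_on_quadratics_including_edges(self):
        axis = fs.WavenumberAxis(np.arange(1.0, 101.0))  # unit step
        a = 0.37
        s = fs.Spectrum(axis, a * axis.values**2)
        d2 = fs.savgol(s, 7, 2, 2)
        assert np.allclose(d2.intensity, 2 * a, atol=1e-8)

    def test_gaussian_second_derivative_known_window_bias(self, uniform_axis):
        """sigma=10 at step 4: frozen scipy-oracle value; the quadratic
        7-point window underestimates the analytic -0.01 by ~30%."""
        y = np.exp(-0.5 * ((uniform_axis.values - 1650) / 10.0) ** 2)
        d2 = fs.savgol(fs.Spectrum(uniform_axis, y), 7, 2, 2)
        i = int(np.argmin(np.abs(uniform_axis.values - 1650)))
        assert d2.intensity[i] == pytest.approx(-0.0069512, abs=1e-6)

    def test_linearity(self, uniform_axis, rng):
        x1 = rng.normal(size=len(uniform_axis))
        x2 = rng.normal(size=len(uniform_axis))
        a, b = 1.3, -0.6
        lhs = savgol_matrix(uniform_axis, (a * x1 + b * x2)[None, :], 7, 2, 2)[0]
        rhs = (
            a * savgol_matrix(uniform_axis, x1[None, :], 7, 2, 2)[0]
            + b * savgol_matrix(uniform_axis, x2[None, :], 7, 2, 2)[0]
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_segment_shorter_than_window_errors(self):
        axis = fs.WavenumberAxis(np.arange(1000.0, 1020.0, 4.0))
        with pytest.raises(fs.SpectraError, match="shorter than window"):
            fs.savgol(fs.Spectrum(axis, np.ones(5)), 7, 2, 2)


class TestVectorNormalize:
    def test_three_four_five(self):
        axis = fs.WavenumberAxis([1000.0, 1010.0])
        out = fs.vector_normalize(fs.Spectrum(axis, [3.0, 4.0]))
        assert np.allclose(out.intensity, [0.6, 0.8])

    def test_unit_norm_input_unchanged_and_property(self, uniform_axis, rng):
        for _ in range(5):
            y = rng.normal(size=len(uniform_axis))
            out = fs.vector_normalize(fs.Spectrum(uniform_axis, y))
            assert np.linalg.norm(out.intensity) == pytest.approx(1.0)
        unit = fs.vector_normalize(fs.Spectrum(uniform_axis, y))
        again = fs.vector_normalize(unit)
        assert np.allclose(again.intensity, unit.intensity, atol=1e-12)

    def test_zero_vector_errors(self, uniform_axis):
        with pytest.raises(fs.SpectraError):
            fs.vector_normalize(fs.Spectrum(uniform_axis, np.zeros(len(uniform_axis))))


class TestPreprocessSample:
    def test_noise_free_sample_recovers_band_model(self, quiet_config):
        # degenerate case: no baseline, no ripple, no noise; the reference is
        # the sample's own truth spectrum, so the EMSC fit is exact and the
        # check isolates the rest of the chain
        cfg = fs.SyntheticCohortConfig(
            **{**quiet_config.__dict__, "baseline_coeffs": ()}
        )
        img, truth = fs.generate_cell_image(cfg, "CTRL", 7)
        rec, _ = fs.preprocess_sample(img, truth.spectrum)
        model = fs.excise_region(truth.spectrum, 2000, 2700).intensity
        got = rec.mean_absorbance.intensity
        cos = got @ model / (np.linalg.norm(got) * np.linalg.norm(model))
        assert cos >= 0.999

    def test_noise_free_sample_with_gel_reference_close_to_model(self, quiet_config):
        # with the protein/carbohydrate gel reference the EMSC legitimately
        # shrinks band structure absent from the reference; recovery stays
        # close but not exact
        cfg = fs.SyntheticCohortConfig(
            **{**quiet_config.__dict__, "baseline_coeffs": ()}
        )
        img, truth = fs.generate_cell_image(cfg, "CTRL", 7)
        ref = fs.generate_reference_spectrum(cfg.axis())
        rec, _ = fs.preprocess_sample(img, ref)
        model = fs.excise_region(truth.spectrum, 2000, 2700).intensity
        got = rec.mean_absorbance.intensity
        cos = got @ model / (np.linalg.norm(got) * np.linalg.norm(model))
        assert cos >= 0.98

    def test_identical_images_give_identical_records(self, small_noisy_config):
        img, _ = fs.generate_cell_image(small_noisy_config, "ALS", 13)
        ref = fs.generate_reference_spectrum(small_noisy_config.axis())
        r1, _ = fs.preprocess_sample(img, ref)
        r2, _ = fs.preprocess_sample(img, ref)
        assert np.array_equal(r1.mean_absorbance.intensity, r2.mean_absorbance.intensity)
        assert np.array_equal(r1.second_derivative.intensity, r2.second_derivative.intensity)

    def test_alt_derivative_preset_changes_deriv_not_absorbance(self, small_noisy_config):
        img, _ = fs.generate_cell_image(small_noisy_config, "MS", 31)
        ref = fs.generate_reference_spectrum(small_noisy_config.axis())
        default = fs.PreprocessParams()
        alt = fs.PreprocessParams(deriv=ALT_DERIV_PRESET)
        r1, _ = fs.preprocess_sample(img, ref, default)
        r2, _ = fs.preprocess_sample(img, ref, alt)
        assert np.array_equal(r1.mean_absorbance.intensity, r2.mean_absorbance.intensity)
        assert not np.array_equal(r1.second_derivative.intensity, r2.second_derivative.intensity)
        assert np.linalg.norm(r2.mean_absorbance.intensity) == pytest.approx(1.0)
        assert np.linalg.norm(r2.second_derivative.intensity) == pytest.approx(1.0)
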