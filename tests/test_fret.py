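"""Index-pipeline operations against oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretsplice.cohort import default_calibration
from fretsplice.fret import (
    CalibrationParams,
    ChannelStack,
    FretDataError,
    bin_image,
    compute_fret_index,
    compute_fret_map,
    correct_bleedthrough,
    median_filter_3x3,
    propagate_uncertainty,
    subtract_background,
    threshold_pixels,
)
from fretsplice.synthetic import ForwardModelParams, generate_fret_stack, make_embryo_scene


def _stack(ID, IA, IF, bg=0.0):
    return ChannelStack(
        ID=np.asarray(ID, dtype=float),
        IA=np.asarray(IA, dtype=float),
        IF=np.asarray(IF, dtype=float),
        background={"ID": bg, "IA": bg, "IF": bg},
    )


class TestBinImage:
    def test_constant_image_preserved(self):
        out = bin_image(np.full((8, 10), 7.0), 2)
        assert out.shape == (4, 5)
        assert np.all(out == 7.0)

    def test_block_mean(self):
        out = bin_image(np.array([[1.0, 2.0], [3.0, 4.0]]), 2)
        assert out.shape == (1, 1)
        assert out[0, 0] == 2.5

    def test_factor_one_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(bin_image(img, 1), img)

    def test_trailing_pixels_cropped(self):
        out = bin_image(np.ones((5, 7)), 2)
        assert out.shape == (2, 3)

    def test_invalid_factor(self):
        with pytest.raises(FretDataError):
            bin_image(np.ones((4, 4)), 0)


class TestBackground:
    def test_scalar_subtraction(self):
        out = subtract_background(_stack(np.full((2, 2), 100.0),
                                         np.full((2, 2), 100.0),
                                         np.full((2, 2), 100.0), bg=20.0))
        assert np.all(out.ID == 80.0)

    def test_zero_background_identity(self):
        out = subtract_background(_stack(np.full((2, 2), 10.0),
                                         np.full((2, 2), 10.0),
                                         np.full((2, 2), 10.0), bg=0.0))
        assert np.all(out.ID == 10.0)

    def test_negative_values_retained_not_clipped(self):
        out = subtract_background(_stack(np.full((2, 2), 10.0),
                                         np.full((2, 2), 10.0),
                                         np.full((2, 2), 10.0), bg=20.0))
        assert np.all(out.ID == -10.0)

    def test_missing_background_is_error(self):
        stack = ChannelStack(ID=np.ones((2, 2)), IA=np.ones((2, 2)), IF=np.ones((2, 2)))
        with pytest.raises(FretDataError, match="background"):
            subtract_background(stack)


class TestBleedthrough:
    def test_direct_arithmetic(self):
        cF = correct_bleedthrough(np.array([[100.0]]), np.array([[50.0]]),
                                  np.array([[80.0]]), alpha=0.5, delta=0.2)
        assert cF[0, 0] == pytest.approx(100 - 10 - 40)

    def test_zero_factors_identity(self):
        IF = np.random.default_rng(0).uniform(0, 100, (4, 4))
        np.testing.assert_array_equal(
            correct_bleedthrough(IF, np.ones((4, 4)), np.ones((4, 4)), 0.0, 0.0), IF
        )

    def test_overcorrection_retained_negative(self):
        cF = correct_bleedthrough(np.array([[10.0]]), np.array([[100.0]]),
                                  np.array([[0.0]]), alpha=0.0, delta=0.2)
        assert cF[0, 0] == pytest.approx(-10.0)

    def test_shape_mismatch(self):
        with pytest.raises(FretDataError, match="shape"):
            correct_bleedthrough(np.ones((2, 2)), np.ones((3, 2)), np.ones((2, 2)), 0, 0)


class TestFretIndex:
    def test_zero_sensitized_emission(self):
        F, valid = compute_fret_index(np.array([0.0]), np.array([100.0]), 1.0, 1.0)
        assert F[0] == 0.0 and valid[0]

    def test_symmetry_point(self):
        F, _ = compute_fret_index(np.array([100.0]), np.array([100.0]), 1.0, 1.0)
        assert F[0] == pytest.approx(0.5)

    def test_scaled_numerator(self):
        F, _ = compute_fret_index(np.array([50.0]), np.array([100.0]), 2.0, 1.0)
        assert F[0] == pytest.approx(0.5)

    def test_nonpositive_donor_invalid(self):
        F, valid = compute_fret_index(np.array([10.0, 10.0]), np.array([0.0, -5.0]), 1.0, 1.0)
        assert not valid.any()
        assert np.isnan(F).all()

    def test_bounded_for_nonnegative_cf(self, rng):
        cF = rng.uniform(0, 1e4, 500)
        qD = rng.uniform(1e-3, 1e4, 500)
        F, valid = compute_fret_index(cF, qD, 0.8, 1.3)
        assert valid.all()
        assert np.all((F >= 0) & (F <= 1))

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_cf_and_qd(self, cF, qD, bump):
        F0, _ = compute_fret_index(np.array([cF]), np.array([qD]), 0.9, 1.1)
        F1, _ = compute_fret_index(np.array([cF + bump]), np.array([qD]), 0.9, 1.1)
        F2, _ = compute_fret_index(np.array([cF]), np.array([qD + bump]), 0.9, 1.1)
        assert F1[0] > F0[0]
        assert F2[0] < F0[0]


def _brute_force_median3(img):
    pad = np.pad(img, 1, mode="reflect")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = pad[i : i + 3, j : j + 3].ravel()
            window = window[~np.isnan(window)]
            out[i, j] = np.median(window) if window.size else np.nan
    return out


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((6, 6), 0.4)
        np.testing.assert_array_equal(median_filter_3x3(img), img)

    def test_single_outlier_removed(self):
        img = np.full((5, 5), 0.2)
        img[2, 2] = 1.0
        assert median_filter_3x3(img)[2, 2] == pytest.approx(0.2)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        np.testing.assert_allclose(median_filter_3x3(img), _brute_force_median3(img))

    def test_nan_neighbours_ignored(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        img[::3, ::4] = np.nan
        np.testing.assert_allclose(median_filter_3x3(img), _brute_force_median3(img))


class TestUncertainty:
    CAL = CalibrationParams(alpha=0.3, delta=0.15, QD=0.85, phi_ratio=1.2)

    def _uniform_stack(self, scale=1.0):
        bg = 100.0 * scale
        return _stack(np.full((3, 3), 1500.0 * scale),
                      np.full((3, 3), 2100.0 * scale),
                      np.full((3, 3), 1400.0 * scale), bg=bg)

    def test_vanishes_with_noise_gain(self):
        sig = propagate_uncertainty(self._uniform_stack(), self.CAL, noise_gain=1e-12)
        assert np.nanmax(sig) < 1e-5

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(FretDataError):
            propagate_uncertainty(self._uniform_stack(), self.CAL, noise_gain=0.0)

    def test_poisson_scaling_halves_sigma(self):
        # scaling every channel (and background) by 4 leaves F fixed but
        # doubles each absolute SD, so the relative error — and sigmaF — halves
        s1 = propagate_uncertainty(self._uniform_stack(1.0), self.CAL)
        s4 = propagate_uncertainty(self._uniform_stack(4.0), self.CAL)
        np.testing.assert_allclose(s4, s1 / 2.0, rtol=1e-12)

    def test_decreases_with_intensity_at_fixed_f(self):
        sigmas = [propagate_uncertainty(self._uniform_stack(s), self.CAL)[0, 0, 0]
                  for s in (0.5, 1.0, 2.0, 8.0)]
        assert np.all(np.diff(sigmas) < 0)

    def test_monte_carlo_oracle(self, rng):
        """Analytic sigmaF vs Poisson resampling through the pipeline."""
        cal = self.CAL
        for scale in (0.5, 1.0, 4.0):
            ID0, IA0, IF0, bg = 1500.0 * scale, 2100.0 * scale, 1400.0 * scale, 100.0 * scale
            n = 20000
            ID = rng.poisson(ID0, n).astype(float)
            IA = rng.poisson(IA0, n).astype(float)
            IF = rng.poisson(IF0, n).astype(float)
            cF = (IF - bg) - cal.delta * (ID - bg) - cal.alpha * (IA - bg)
            qD = ID - bg
            F, _ = compute_fret_index(cF, qD, cal.QD, cal.phi_ratio)
            mc = np.nanstd(F)
            analytic = propagate_uncertainty(
                _stack(np.array([[ID0]]), np.array([[IA0]]), np.array([[IF0]]), bg=bg),
                cal,
            )[0, 0, 0]
            assert analytic == pytest.approx(mc, rel=0.1)


class TestThreshold:
    def test_synthetic_scene_mask_selects_cortex(self, poisson_params):
        scene = make_embryo_scene(seed=21)
        stack, _ = generate_fret_stack(scene, poisson_params, n_frames=1)
        calib = default_calibration(poisson_params, bin_factor=1)
        mask = threshold_pixels(stack, calib)[0]
        assert mask[scene.cortex_mask].mean() >= 0.90
        assert mask[~scene.embryo_mask].mean() <= 0.05

    def test_all_below_threshold_warns_empty(self):
        stack = _stack(np.full((4, 4), 5.0), np.full((4, 4), 5.0),
                       np.full((4, 4), 5.0), bg=100.0)
        calib = CalibrationParams(alpha=0.1, delta=0.1, QD=0.9, phi_ratio=1.0)
        with pytest.warns(UserWarning, match="empty mask"):
            mask = threshold_pixels(stack, calib)
        assert not mask.any()

    def test_zero_k_zero_background_passes_sensor_pixels(self, noiseless_params, scene):
        p = ForwardModelParams(noise="none", background=0.0)
        stack, _ = generate_fret_stack(scene, p, n_frames=1)
        calib = CalibrationParams(alpha=p.alpha, delta=p.delta, QD=p.QD,
                                  phi_ratio=p.phi_ratio, threshold_k=0.0)
        mask = threshold_pixels(stack, calib)[0]
        assert mask[scene.cortex_mask].all()


class TestPipelineInvariants:
    def test_common_scaling_leaves_f_unchanged(self, noiseless_run, scene):
        stack, _, calib = noiseless_run
        scaled = ChannelStack(
            ID=stack.ID * 3.0, IA=stack.IA * 3.0, IF=stack.IF * 3.0,
            background={k: 3.0 * v for k, v in stack.background.items()},
        )
        f1 = compute_fret_map(stack, calib, apply_median=False)
        f2 = compute_fret_map(scaled, calib, apply_median=False)
        sel = scene.cortex_mask
        np.testing.assert_allclose(f2.F[0][sel], f1.F[0][sel], rtol=1e-9)

    def test_bleedthrough_correction_exactly_invertible(self, scene):
        """alpha, delta > 0 with zero noise must still recover truth exactly."""
        p = ForwardModelParams(noise="none", alpha=0.45, delta=0.3)
        stack, truth = generate_fret_stack(scene, p, n_frames=1)
        fmap = compute_fret_map(stack, default_calibration(p, bin_factor=1),
                                apply_median=False)
        sel = scene.cortex_mask
        assert np.nanmax(np.abs(fmap.F[0][sel] - truth[sel])) < 1e-12

    def test_zero_bleedthrough_round_trip(self, scene):
        p = ForwardModelParams(noise="none", alpha=0.0, delta=0.0, background=0.0)
        stack, truth = generate_fret_stack(scene, p, n_frames=1)
        fmap = compute_fret_map(stack, default_calibration(p, bin_factor=1),
                                apply_median=False)
        sel = scene.cortex_mask
        assert np.nanmax(np.abs(fmap.F[0][sel] - truth[sel])) < 1e-12

    def test_binned_pipeline_recovers_constant_efficiency(self):
        # constant-E cortex: block-averaging mixes only pixels of equal truth,
        # so the 2x2-binned default still reads the exact efficiency
        p = ForwardModelParams(noise="none")
        scene = make_embryo_scene(construct="N-TSMod", seed=2)
        stack, truth = generate_fret_stack(scene, p, n_frames=1)
        fmap = compute_fret_map(stack, default_calibration(p, bin_factor=2),
                                apply_median=False)
        vals = fmap.F[0][fmap.valid_mask[0]]
        assert len(vals) > 50
        np.testing.assert_allclose(vals, p.E0, atol=1e-12)
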