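import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticox.errors import EmptyResultError, OutOfModelError, ParameterError
from corticox.speckle import (
    ContrastImage,
    FlowMap,
    SpeckleModelParams,
    average_contrast,
    compute_contrast,
    contrast_from_tau,
    debias_contrast,
    flow_map,
    invert_contrast,
    relative_flow,
)

from conftest import naive_contrast

# K at x = T/tau_c = 1 with beta = 1: sqrt((exp(-2) + 1) / 2)
K_AT_X1 = 0.7534372181000262


class TestComputeContrast:
    def test_constant_frame_zero_contrast(self):
        img = compute_contrast(np.full((32, 32), 100.0), window=7)
        assert np.all(img.K[img.valid_mask] == 0.0)

    def test_center_matches_direct_evaluation(self):
        patch = np.arange(1.0, 50.0).reshape(7, 7)
        vals = np.arange(1.0, 50.0)
        expected = vals.std(ddof=0) / vals.mean()
        img = compute_contrast(patch, window=7)
        assert img.K[3, 3] == pytest.approx(expected, rel=1e-12)
        assert img.valid_mask[3, 3]

    def test_default_window_is_seven(self):
        # default acquisition: 7x7 window, 5 ms exposure
        img = compute_contrast(np.ones((16, 16)), exposure_T=5e-3)
        assert img.window == 7
        assert img.exposure_T == 5e-3

    def test_border_flagged_invalid(self):
        img = compute_contrast(np.random.default_rng(0).random((20, 20)), window=7)
        assert not img.valid_mask[:3].any()
        assert not img.valid_mask[:, -3:].any()
        assert np.isnan(img.K[0, 0])

    @pytest.mark.parametrize("window", [2, 4, 1, -3])
    def test_even_or_small_window_rejected(self, window):
        with pytest.raises(ParameterError):
            compute_contrast(np.ones((16, 16)), window=window)

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(ParameterError):
            compute_contrast(np.ones((5, 5)), window=7)

    def test_zero_mean_pixel_flagged_not_raised(self):
        frame = np.ones((16, 16))
        frame[4:12, 4:12] = 0.0  # window mean of zero in the middle
        img = compute_contrast(frame, window=7)
        assert not img.valid_mask[7, 7]
        assert np.isnan(img.K[7, 7])

    def test_fast_path_matches_naive_oracle(self, rng):
        for _ in range(100):
            frame = rng.gamma(2.0, 50.0, size=(64, 64))
            img = compute_contrast(frame, window=7)
            oracle = naive_contrast(frame, 7)
            ok = img.valid_mask
            np.testing.assert_allclose(img.K[ok], oracle[ok], rtol=1e-12, atol=0)

    @pytest.mark.parametrize("window", [3, 5, 9])
    def test_oracle_equivalence_other_windows(self, window, rng):
        frame = rng.random((40, 47)) * 1000
        img = compute_contrast(frame, window=window)
        oracle = naive_contrast(frame, window)
        ok = img.valid_mask
        np.testing.assert_allclose(img.K[ok], oracle[ok], rtol=1e-12, atol=0)


class TestAverageContrast:
    def _img(self, value, shape=(16, 16)):
        frame = np.full(shape, 1.0)
        img = compute_contrast(frame, window=7, exposure_T=5e-3)
        img.K[img.valid_mask] = value
        return img

    def test_mean_of_identical_is_identity(self):
        imgs = [self._img(0.3) for _ in range(5)]
        avg = average_contrast(imgs, n=5)
        np.testing.assert_array_equal(avg.K[avg.valid_mask], 0.3)
        assert avg.n_averaged == 5

    def test_arithmetic_mean(self):
        avg = average_contrast([self._img(0.2), self._img(0.4)])
        assert avg.K[8, 8] == pytest.approx(0.3)

    def test_invalid_pixels_propagate(self):
        a, b = self._img(0.2), self._img(0.4)
        b.valid_mask[8, 8] = False
        avg = average_contrast([a, b])
        assert not avg.valid_mask[8, 8]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            average_contrast([])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            average_contrast([self._img(0.2), self._img(0.2, shape=(20, 20))])

    def test_n_45_matches_default_processing(self):
        imgs = [self._img(0.5) for _ in range(45)]
        assert average_contrast(imgs, n=45).n_averaged == 45


class TestForwardModel:
    def test_long_tau_limit_is_sqrt_beta(self, params):
        assert contrast_from_tau(1e3, params) == pytest.approx(1.0, abs=1e-5)
        quarter = SpeckleModelParams(exposure_T=5e-3, beta=0.25)
        assert contrast_from_tau(1e3, quarter) == pytest.approx(0.5, abs=1e-5)

    def test_value_at_x_equal_one(self, params):
        assert contrast_from_tau(5e-3, params) == pytest.approx(K_AT_X1, rel=1e-12)

    def test_nonpositive_tau_rejected(self, params):
        with pytest.raises(ParameterError):
            contrast_from_tau(0.0, params)
        with pytest.raises(ParameterError):
            contrast_from_tau(-1e-3, params)

    def test_strictly_increasing_in_tau(self, params):
        taus = np.logspace(-7, 0, 400)
        ks = contrast_from_tau(taus, params)
        assert np.all(np.diff(ks) > 0)

    def test_series_matches_high_precision_direct(self, params):
        # high-precision oracle for (exp(-2x) - 1 + 2x) / (2 x^2)
        import sympy

        from corticox.speckle import _model_ratio

        for x in np.logspace(-6, -3, 40):
            xs = sympy.Float(float(x), 50)
            exact = float((sympy.exp(-2 * xs) - 1 + 2 * xs) / (2 * xs**2))
            assert _model_ratio(np.array([x]))[0] == pytest.approx(exact, rel=1e-10)

    def test_series_direct_agree_near_threshold(self):
        # both branches evaluated at the same x around the switch point
        for x in [5e-4, 1e-3, 2e-3]:
            series = 1.0 - (2 / 3) * x + (1 / 3) * x**2 - (2 / 15) * x**3
            direct = (np.expm1(-2.0 * x) + 2.0 * x) / (2.0 * x**2)
            assert series == pytest.approx(direct, rel=1e-10)


class TestInvertContrast:
    def test_roundtrip_at_x_equal_one(self, params):
        assert invert_contrast(K_AT_X1, params) == pytest.approx(5e-3, rel=1e-9)

    def test_k_at_sqrt_beta_is_out_of_model(self, params):
        with pytest.raises(OutOfModelError):
            invert_contrast(1.0, params)
        with pytest.raises(OutOfModelError):
            invert_contrast(1.2, params)

    def test_nonpositive_k_rejected(self, params):
        with pytest.raises(ParameterError):
            invert_contrast(0.0, params)
        with pytest.raises(ParameterError):
            invert_contrast(-0.5, params)

    def test_roundtrip_over_six_decades(self, params):
        taus = np.logspace(-6, -1, 50)
        for tau in taus:
            k = contrast_from_tau(tau, params)
            assert invert_contrast(k, params) == pytest.approx(tau, rel=1e-9)

    @given(
        k=st.floats(min_value=0.01, max_value=0.99),
        k2=st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_k(self, k, k2):
        params = SpeckleModelParams(exposure_T=5e-3)
        if k == k2:
            return
        lo, hi = sorted([k, k2])
        assert invert_contrast(lo, params) < invert_contrast(hi, params)


class TestFlowMap:
    def _uniform_contrast(self, value, shape=(24, 24)):
        k = np.full(shape, value)
        valid = np.ones(shape, dtype=bool)
        return ContrastImage(K=k, window=7, valid_mask=valid, exposure_T=5e-3)

    def test_uniform_k_gives_uniform_tau(self):
        fmap = flow_map(self._uniform_contrast(K_AT_X1))
        np.testing.assert_allclose(fmap.tau_c[fmap.valid_mask], 5e-3, rtol=1e-9)

    def test_out_of_range_pixel_isolated(self):
        img = self._uniform_contrast(K_AT_X1)
        img.K[5, 5] = 1.2
        fmap = flow_map(img)
        assert not fmap.valid_mask[5, 5]
        assert np.isnan(fmap.tau_c[5, 5])
        assert np.isfinite(fmap.tau_c[fmap.valid_mask]).all()

    def test_beta_defaults_to_one(self):
        # inversion without explicit params must assume beta = 1
        fmap = flow_map(self._uniform_contrast(K_AT_X1))
        assert fmap.tau_c[12, 12] == pytest.approx(5e-3, rel=1e-9)

    def test_icr_is_reciprocal(self):
        fmap = flow_map(self._uniform_contrast(0.6))
        ok = fmap.valid_mask
        np.testing.assert_allclose(fmap.icr[ok], 1.0 / fmap.tau_c[ok], rtol=1e-12)

    def test_no_valid_pixels_rejected(self):
        img = self._uniform_contrast(0.5)
        img.valid_mask[:] = False
        with pytest.raises(EmptyResultError):
            flow_map(img)


class TestDebias:
    def test_double_application_rejected(self):
        img = ContrastImage(
            K=np.full((16, 16), 0.5),
            window=7,
            valid_mask=np.ones((16, 16), bool),
            exposure_T=5e-3,
        )
        once = debias_contrast(img)
        with pytest.raises(ParameterError):
            debias_contrast(once)

    def test_correction_matches_measured_bias(self, rng):
        # gamma frames at known K*: raw median matches the predicted
        # first-order bias K*(1 - 3(1+K^2)/(4N)); debiased median ~ K*.
        k_star = K_AT_X1
        shape_par = 1.0 / k_star**2
        imgs = []
        for _ in range(60):
            frame = rng.gamma(shape_par, 100.0, size=(96, 96))
            imgs.append(compute_contrast(frame, window=7, exposure_T=5e-3))
        avg = average_contrast(imgs)
        raw_median = np.median(avg.K[avg.valid_mask])
        predicted = k_star * (1.0 - 0.75 * (1.0 + k_star**2) / 49.0)
        assert raw_median == pytest.approx(predicted, rel=5e-3)
        fixed = debias_contrast(avg)
        assert np.median(fixed.K[fixed.valid_mask]) == pytest.approx(k_star, rel=5e-3)


class TestRelativeFlow:
    def _flow(self, tau, shape=(32, 32)):
        return FlowMap(
            tau_c=np.full(shape, tau),
            valid_mask=np.ones(shape, dtype=bool),
            exposure_T=5e-3,
        )

    def _rois(self, shape=(32, 32)):
        a = np.zeros(shape, bool)
        a[4:12, 4:12] = True
        b = np.zeros(shape, bool)
        b[20:28, 20:28] = True
        return {"A": a, "B": b}

    def test_baseline_vs_itself_is_one(self):
        base = self._flow(4e-3)
        result = relative_flow(base, base, self._rois())
        assert result == {"A": 1.0, "B": 1.0}

    def test_doubled_tau_halves_flow(self):
        base = self._flow(4e-3)
        current = self._flow(8e-3)
        result = relative_flow(current, base, self._rois())
        assert result["A"] == pytest.approx(0.5)
        assert result["B"] == pytest.approx(0.5)

    def test_empty_roi_warned_and_missing(self):
        base = self._flow(4e-3)
        current = self._flow(4e-3)
        current.valid_mask[4:12, 4:12] = False
        with pytest.warns(UserWarning, match="'A'"):
            result = relative_flow(current, base, self._rois())
        assert "A" not in result and "B" in result

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            relative_flow(self._flow(1e-3), self._flow(1e-3, shape=(16, 16)), {})


class TestEstimatorRecovery:
    def test_uniform_tau_recovered_within_3_percent(self):
        from corticox.simulate import SpeckleScenario, synth_speckle_stack

        scen = SpeckleScenario(tau_c_map=np.full((96, 96), 5e-3), n_frames=45, seed=42)
        stack, truth = synth_speckle_stack(scen)
        imgs = [
            compute_contrast(f, window=7, exposure_T=5e-3) for f in stack.frames
        ]
        avg = debias_contrast(average_contrast(imgs))
        fmap = flow_map(avg)
        median = np.median(fmap.tau_c[fmap.valid_mask])
        assert median == pytest.approx(5e-3, rel=0.03)

    def test_simulated_occlusion_roi(self):
        # tau doubled inside (a dilation of) the target ROI only
        from scipy.ndimage import binary_dilation

        from corticox.simulate import SpeckleScenario, synth_speckle_stack

        shape = (160, 160)
        target = np.zeros(shape, bool)
        target[40:80, 40:80] = True
        other = np.zeros(shape, bool)
        other[100:140, 100:140] = True
        tau0 = 2.5e-3
        tau_map = np.full(shape, tau0)
        tau_map[binary_dilation(target, iterations=3)] = 2 * tau0

        def recover(tmap, seed):
            scen = SpeckleScenario(tau_c_map=tmap, n_frames=90, seed=seed)
            stack, _ = synth_speckle_stack(scen)
            imgs = [compute_contrast(f, 7, exposure_T=5e-3) for f in stack.frames]
            return flow_map(debias_contrast(average_contrast(imgs)))

        base = recover(np.full(shape, tau0), seed=3)
        current = recover(tau_map, seed=4)
        result = relative_flow(current, base, {"target": target, "other": other})
        assert result["target"] == pytest.approx(0.5, rel=0.02)
        assert result["other"] == pytest.approx(1.0, rel=0.02)
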