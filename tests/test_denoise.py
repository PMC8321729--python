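"""Thresholding rules, noise estimation, detail enhancement, and the
end-to-end denoise/enhance pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wtie import (
    EnhanceParams,
    PhantomSpec,
    ThresholdPolicy,
    WtieConfig,
    apply_threshold,
    dwt2,
    enhance_details,
    estimate_noise_sigma,
    hard_threshold,
    idwt2,
    make_phantom,
    psnr,
    soft_threshold,
    visu_shrink_threshold,
    wtie_enhance,
)

finite = st.floats(-1e6, 1e6, allow_nan=False)
nonneg = st.floats(0.0, 1e6, allow_nan=False)


class TestThresholdRules:
    @pytest.mark.parametrize(
        "fn,a,s,expected",
        [
            (hard_threshold, 5.0, 3.0, 5.0),   # keep branch
            (hard_threshold, 2.0, 3.0, 0.0),   # kill branch
            (hard_threshold, -5.0, 3.0, -5.0),
            (soft_threshold, 5.0, 3.0, 2.0),   # shrink branch
            (soft_threshold, -5.0, 3.0, -2.0),
            (soft_threshold, 2.0, 3.0, 0.0),
            (hard_threshold, -7.3, 0.0, -7.3), # zero threshold is identity
            (soft_threshold, -7.3, 0.0, -7.3),
        ],
    )
    def test_closed_form_values(self, fn, a, s, expected):
        assert fn(a, s) == pytest.approx(expected)

    @pytest.mark.parametrize("fn", [hard_threshold, soft_threshold])
    def test_negative_threshold_rejected(self, fn):
        with pytest.raises(ValueError, match="nonnegative"):
            fn(1.0, -0.5)

    @settings(derandomize=True, max_examples=200)
    @given(a=finite, s=nonneg)
    def test_soft_is_a_contraction_and_hard_preserves_sign(self, a, s):
        assert abs(soft_threshold(a, s)) <= abs(a) + 1e-12
        h = hard_threshold(a, s)
        assert h == 0.0 or np.sign(h) == np.sign(a)

    @settings(derandomize=True, max_examples=200)
    @given(a=finite, s1=nonneg, s2=nonneg)
    def test_zero_set_grows_with_threshold(self, a, s1, s2):
        lo, hi = min(s1, s2), max(s1, s2)
        for fn in (hard_threshold, soft_threshold):
            if fn(a, lo) == 0.0:
                assert fn(a, hi) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(a=finite, s=nonneg)
    def test_hard_threshold_idempotent(self, a, s):
        assert hard_threshold(hard_threshold(a, s), s) == hard_threshold(a, s)


class TestUniversalThreshold:
    def test_closed_forms(self):
        assert visu_shrink_threshold(1.23, 1) == 0.0          # ln 1 = 0
        assert visu_shrink_threshold(0.0, 1000) == 0.0
        assert visu_shrink_threshold(2.0, 65536) == pytest.approx(9.4193, abs=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            visu_shrink_threshold(-1.0, 10)
        with pytest.raises(ValueError):
            visu_shrink_threshold(1.0, 0)

    def test_policy_records_its_derivation(self):
        p = ThresholdPolicy.visu_shrink("soft", 2.0, 65536)
        assert p.threshold == pytest.approx(2.0 * np.sqrt(2 * np.log(65536)), abs=1e-12)
        assert p.sigma_m == 2.0 and p.signal_length == 65536


class TestNoiseEstimation:
    def test_zero_for_noise_free_constant_image(self):
        sb = dwt2(np.full((64, 64), 0.5), "haar", 2)
        assert estimate_noise_sigma(sb) == 0.0

    def test_consistent_on_pure_gaussian_noise(self):
        # MAD of the finest diagonal subband recovers sigma within 10%
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.0, 0.1, size=(256, 256))
            estimates.append(estimate_noise_sigma(dwt2(x, "haar", 1)))
        assert np.all(np.abs(np.array(estimates) - 0.1) < 0.01)


class TestApplyThreshold:
    def test_zero_threshold_leaves_subbands_unchanged(self, rng):
        sb = dwt2(rng.random((16, 16)), "db4", 2)
        out = apply_threshold(sb, ThresholdPolicy("soft", 0.0))
        for j, o, g in out.iter_details():
            np.testing.assert_array_equal(g, sb.detail(j, o))

    def test_huge_threshold_leaves_approximation_only(self, rng):
        x = rng.random((16, 16))
        sb = dwt2(x, "haar", 1)
        out = apply_threshold(sb, ThresholdPolicy("hard", np.inf))
        for _, _, g in out.iter_details():
            assert np.all(g == 0.0)
        np.testing.assert_array_equal(out.approx, sb.approx)

    def test_hard_rule_on_2x2_haar_coefficients(self):
        sb = dwt2(np.array([[1.0, 2.0], [3.0, 4.0]]), "haar", 1)
        out = apply_threshold(sb, ThresholdPolicy("hard", 1.5))
        assert out.detail(1, "horizontal") == pytest.approx(-2.0)
        assert out.detail(1, "vertical") == pytest.approx(0.0)
        assert out.detail(1, "diagonal") == pytest.approx(0.0)
        assert out.approx == pytest.approx(5.0)  # approximation untouched

    def test_input_subbands_not_mutated(self, rng):
        sb = dwt2(rng.random((16, 16)), "haar", 1)
        before = sb.detail(1, "diagonal").copy()
        apply_threshold(sb, ThresholdPolicy("soft", 10.0))
        np.testing.assert_array_equal(sb.detail(1, "diagonal"), before)


class TestEnhanceDetails:
    def test_identity_params_change_nothing(self, rng):
        sb = dwt2(rng.random((16, 16)), "haar", 2)
        out = enhance_details(sb, EnhanceParams())
        for j, o, g in out.iter_details():
            np.testing.assert_array_equal(g, sb.detail(j, o))

    def test_linear_map_applied_to_targets_only(self, rng):
        sb = dwt2(rng.random((16, 16)), "haar", 2)
        out = enhance_details(
            sb, EnhanceParams(gain=2.0, offset=1.0, target_levels=[1],
                              target_orientations=["diagonal"])
        )
        np.testing.assert_allclose(
            out.detail(1, "diagonal"), 2.0 * sb.detail(1, "diagonal") + 1.0
        )
        np.testing.assert_array_equal(out.detail(2, "diagonal"), sb.detail(2, "diagonal"))
        np.testing.assert_array_equal(out.detail(1, "horizontal"), sb.detail(1, "horizontal"))
        np.testing.assert_array_equal(out.approx, sb.approx)

    def test_zero_gain_zero_offset_zeroes_targets(self, rng):
        sb = dwt2(rng.random((16, 16)), "haar", 1)
        out = enhance_details(sb, EnhanceParams(gain=0.0, offset=0.0))
        for _, _, g in out.iter_details():
            assert np.all(g == 0.0)

    def test_unknown_targets_rejected(self, rng):
        sb = dwt2(rng.random((16, 16)), "haar", 1)
        with pytest.raises(ValueError, match="unknown target level"):
            enhance_details(sb, EnhanceParams(target_levels=[3]))
        with pytest.raises(ValueError, match="unknown orientation"):
            enhance_details(sb, EnhanceParams(target_orientations=["radial"]))


class TestPipeline:
    def test_noise_free_identity_configuration(self, rng):
        x = rng.random((32, 32))
        out = wtie_enhance(x, WtieConfig(sigma=0.0, gain=1.0, offset=0.0, levels=2))
        assert np.max(np.abs(out - x)) < 1e-8

    def test_deterministic_for_fixed_inputs(self, phantom_pair):
        _, _, noisy = phantom_pair
        a = wtie_enhance(noisy, WtieConfig())
        b = wtie_enhance(noisy, WtieConfig())
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("sigma", [0.05, 0.1, 0.2])
    def test_soft_visushrink_improves_psnr(self, sigma):
        wins = 0
        for seed in range(10):
            clean, noisy = make_phantom(PhantomSpec(noise_sigma=sigma, seed=seed))
            out = wtie_enhance(noisy, WtieConfig(mode="soft"))
            if psnr(clean, out) > psnr(clean, noisy):
                wins += 1
        assert wins >= 9

    def test_hard_and_soft_modes_differ_above_threshold(self):
        # a strong isolated edge guarantees coefficients above S
        x = np.zeros((32, 32))
        x[:, 15:] = 1.0
        cfg = dict(sigma=0.02, levels=2, wavelet="haar")
        hard = wtie_enhance(x, WtieConfig(mode="hard", **cfg))
        soft = wtie_enhance(x, WtieConfig(mode="soft", **cfg))
        assert np.max(np.abs(hard - soft)) > 1e-6

    def test_gain_above_one_does_not_reduce_edge_contrast(self):
        x = np.zeros((32, 32))
        x[:, 16:] = 0.6
        base = wtie_enhance(x, WtieConfig(sigma=0.0, gain=1.0, wavelet="haar", levels=2))
        boosted = wtie_enhance(x, WtieConfig(sigma=0.0, gain=1.5, wavelet="haar", levels=2))
        grad = lambda im: np.abs(np.diff(im, axis=1)).sum() + np.abs(np.diff(im, axis=0)).sum()
        assert grad(boosted) >= grad(base) - 1e-9

    def test_report_exposes_resolved_threshold(self, phantom_pair):
        _, _, noisy = phantom_pair
        out, report = wtie_enhance(noisy, WtieConfig(), return_report=True)
        assert report["sigma_source"] == "estimated"
        assert report["threshold"] == pytest.approx(
            report["sigma"] * np.sqrt(2 * np.log(noisy.size))
        )
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_config_validation_lists_every_problem(self):
        cfg = WtieConfig(wavelet="bogus", levels=0, mode="fuzzy", sigma=-1.0)
        with pytest.raises(ValueError) as exc:
            cfg.validate()
        msg = str(exc.value)
        for frag in ("bogus", "levels", "mode", "sigma"):
            assert frag in msg

    def test_out_of_range_image_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            wtie_enhance(np.full((16, 16), 1.5), WtieConfig(levels=1))
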