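import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smcortex import gradients as grad
from smcortex import synthetic as syn


def exp_profile(A=100.0, lam=1.5, length=4.5, step=0.1, background=0.0):
    x = np.arange(0.0, length + step / 2, step)
    return x, A * np.exp(-x / lam) + background


def make_set(intensities, step=0.1):
    intensities = np.atleast_2d(np.asarray(intensities, float))
    x = np.arange(intensities.shape[1]) * step
    return grad.ProfileSet(x=x, intensity=intensities,
                           cell_ids=np.arange(intensities.shape[0]))


class TestAlignProfiles:
    def test_monotone_profile_unchanged(self):
        x, y = exp_profile()
        out = grad.align_profiles([(0, x, y)])
        np.testing.assert_allclose(out.intensity[0], y)
        assert out.x[0] == 0.0

    def test_peak_shift_drops_head(self):
        y = np.array([1.0, 2.0, 3.0, 10.0, 8.0, 6.0, 4.0])
        x = np.arange(7) * 0.1
        out = grad.align_profiles([(0, x, y)])
        np.testing.assert_allclose(out.intensity[0], [10.0, 8.0, 6.0, 4.0])
        assert out.x[0] == 0.0

    def test_jittered_peaks_all_align_to_zero(self):
        rng = np.random.default_rng(0)
        profiles = []
        for cid in range(240):
            shift = rng.integers(0, 8)
            x = np.arange(100) * 0.05
            y = np.concatenate([np.linspace(1, 50, shift), 100 * np.exp(-x / 1.5)])
            profiles.append((cid, np.arange(y.size) * 0.05, y))
        out = grad.align_profiles(profiles)
        assert np.all(np.argmax(out.intensity, axis=1) == 0)

    def test_max_at_last_sample_flagged(self):
        x = np.arange(5) * 0.1
        with pytest.warns(UserWarning, match="no gradient tail"):
            grad.align_profiles([(0, x, np.arange(5.0))])


class TestWindowMeans:
    def test_flat_profile(self):
        x = np.arange(0, 4.01, 0.1)
        y = np.full(x.size, 7.0)
        assert grad.midcell_intensity(x, y) == pytest.approx(7.0)
        assert grad.pole_intensity(x, y) == pytest.approx(7.0)

    def test_midcell_matches_direct_average(self):
        x, y = exp_profile(A=100.0, lam=1.5, length=4.5, step=0.1)
        expected = y[x >= 3.0 - 1e-12].mean()
        assert grad.midcell_intensity(x, y, 1.5) == pytest.approx(expected)

    def test_pole_matches_direct_average(self):
        x, y = exp_profile(step=0.1)
        expected = y[x <= 0.83 + 1e-12].mean()
        assert grad.pole_intensity(x, y, 0.83) == pytest.approx(expected)

    def test_step_profile_pole_value(self):
        x = np.arange(0, 3.01, 0.1)
        y = np.where(x <= 1.0, 50.0, 5.0)
        assert grad.pole_intensity(x, y, 0.83) == pytest.approx(50.0)

    def test_midcell_window_equal_to_length_rejected(self):
        x = np.arange(0, 1.51, 0.1)
        with pytest.raises(ValueError, match="window"):
            grad.midcell_intensity(x, np.ones(x.size), 1.5)

    def test_pole_window_equal_profile_is_whole_mean(self):
        x = np.arange(0, 0.831, 0.083)
        y = np.linspace(10, 1, x.size)
        assert grad.pole_intensity(x, y, 0.83) == pytest.approx(y.mean())


class TestSmoothProfile:
    def test_sigma_zero_identity(self):
        y = np.random.default_rng(1).uniform(0, 10, 50)
        np.testing.assert_array_equal(grad.smooth_profile(y, 0.0, 0.1), y)

    def test_constant_preserved(self):
        y = np.full(60, 3.3)
        np.testing.assert_allclose(grad.smooth_profile(y, 0.5, 0.1), y)

    def test_impulse_matches_discrete_gaussian(self):
        # independent oracle: normalized truncated Gaussian kernel
        n, step, sigma_um = 101, 0.1, 0.2
        y = np.zeros(n)
        y[50] = 1.0
        out = grad.smooth_profile(y, sigma_um, step)
        s = sigma_um / step
        radius = int(4 * s + 0.5)
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / s) ** 2)
        k /= k.sum()
        np.testing.assert_allclose(out[50 - radius : 50 + radius + 1], k, atol=1e-9)


class TestDecayLength:
    @pytest.mark.parametrize("lam", [0.2, 0.5, 1.5, 4.0, 10.0])
    def test_exact_on_noiseless_exponential(self, lam):
        x, y = exp_profile(A=50.0, lam=lam, length=max(3.0, 3 * lam), step=0.05)
        fit = grad.decay_length(x, y)
        assert fit.decay_length_um == pytest.approx(lam, rel=1e-10)
        assert fit.amplitude == pytest.approx(50.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_profile_infinite_lambda(self):
        x = np.arange(0, 3.01, 0.1)
        fit = grad.decay_length(x, np.full(x.size, 5.0))
        assert fit.non_decaying
        assert math.isinf(fit.decay_length_um)

    def test_nonpositive_intensity_rejected(self):
        x = np.arange(0, 3.01, 0.1)
        y = 10.0 * np.exp(-x / 1.0) - 2.0
        with pytest.raises(ValueError, match="background"):
            grad.decay_length(x, y)

    def test_drop_head_excluded_from_fit(self):
        x, y = exp_profile(lam=1.5, length=4.0, step=0.1)
        y[x < 0.5] = y[5]  # corrupt the plateau region only
        fit = grad.decay_length(x, y, drop_head=0.5)
        assert fit.decay_length_um == pytest.approx(1.5, rel=1e-9)

    def test_noisy_averaged_profiles_within_5pct(self):
        model = syn.GradientModel(amplitude_gsd=1.4, decay_length_base=1.5,
                                  noise_frac_sd=0.05)
        profiles, _ = syn.simulate_gradient_profiles(model, 240, 5.0, 0.05, seed=3)
        pset = grad.align_profiles(grad.profiles_from_frame(profiles))
        avg = pset.intensity.mean(axis=0)
        fit = grad.decay_length(pset.x, avg)
        assert fit.decay_length_um == pytest.approx(1.5, rel=0.05)


class TestBufferingCorrelation:
    def _profiles(self, beta, seed=0, n=240):
        model = syn.GradientModel(
            amplitude_gsd=1.8, decay_length_base=1.5, buffering_exponent=beta,
            noise_frac_sd=0.05,
        )
        df, _ = syn.simulate_gradient_profiles(model, n, 5.0, 0.05, seed=seed)
        return grad.align_profiles(grad.profiles_from_frame(df))

    def test_null_model_ci_contains_zero(self):
        out = grad.buffering_correlation(self._profiles(0.0, seed=1))
        assert out.ci_low < 0 < out.ci_high

    def test_buffered_model_significantly_negative(self):
        out = grad.buffering_correlation(self._profiles(0.5, seed=2))
        assert out.correlation < -0.5
        assert out.ci_high < 0

    def test_identical_profiles_rejected(self):
        x, y = exp_profile(step=0.05, length=5.0)
        pset = grad.align_profiles([(i, x, y.copy()) for i in range(60)])
        with pytest.raises(ValueError, match="amplitude variance"):
            grad.buffering_correlation(pset)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError):
            grad.buffering_correlation(self._profiles(0.0, n=10))

    def test_sign_over_replicates(self):
        # beta = 0 -> |median r| < 0.15; beta = 0.5 -> median r < -0.5
        r0, r5 = [], []
        for rep in range(20):
            r0.append(grad.buffering_correlation(self._profiles(0.0, seed=100 + rep),
                                                 n_boot=0).correlation)
            r5.append(grad.buffering_correlation(self._profiles(0.5, seed=200 + rep),
                                                 n_boot=0).correlation)
        assert abs(np.median(r0)) < 0.15
        assert np.median(r5) < -0.5


class TestCvProfile:
    def test_identical_profiles_zero_cv(self):
        x, y = exp_profile(step=0.05, length=5.0)
        pset = grad.align_profiles([(i, x, y.copy()) for i in range(5)])
        out = grad.cv_profile(pset)
        np.testing.assert_allclose(out.cv, 0.0, atol=1e-12)

    def test_scaled_family_constant_cv(self):
        # multiplicative amplitude variation only: CV is x-independent
        rng = np.random.default_rng(4)
        x = np.arange(0, 5.001, 0.05)
        base = 100 * np.exp(-x / 1.5)
        pset = make_set([a * base for a in rng.lognormal(0, 0.3, 50)], step=0.05)
        out = grad.cv_profile(pset)
        assert np.std(out.cv) < 1e-9
        assert out.fold_decrease == pytest.approx(1.0, abs=1e-9)

    def test_buffered_generator_fold_above_one(self):
        # keep the window within ~lambda0/beta so buffering damps (rather
        # than overcompensates) the amplitude variation at the tail
        model = syn.GradientModel(amplitude_gsd=2.0, decay_length_base=1.5,
                                  buffering_exponent=0.3, noise_frac_sd=0.02)
        df, _ = syn.simulate_gradient_profiles(model, 240, 4.0, 0.05, seed=5)
        pset = grad.align_profiles(grad.profiles_from_frame(df))
        out = grad.cv_profile(pset)
        assert out.fold_decrease > 1.0

    def test_zero_mean_flagged(self):
        pset = make_set(np.array([[1.0, 0.0, 1.0], [1.0, 0.0, 1.0], [-2.0, 0.0, 1.0]]))
        out = grad.cv_profile(pset)
        assert np.isnan(out.cv[1])

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            grad.cv_profile(make_set(np.ones((2, 10))))


class TestScaleInvariance:
    @given(scale=st.floats(0.1, 1000.0, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_decay_and_windows(self, scale):
        x, y = exp_profile(A=80.0, lam=1.2, length=4.0, step=0.05)
        fit1 = grad.decay_length(x, y)
        fit2 = grad.decay_length(x, scale * y)
        assert fit2.decay_length_um == pytest.approx(fit1.decay_length_um, rel=1e-9)
        assert grad.midcell_intensity(x, scale * y) == pytest.approx(
            scale * grad.midcell_intensity(x, y), rel=1e-9
        )

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(6)
        mat = rng.uniform(1, 10, size=(8, 40))
        out1 = grad.cv_profile(make_set(mat))
        out2 = grad.cv_profile(make_set(10.0 * mat))
        np.testing.assert_allclose(out1.cv, out2.cv)
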