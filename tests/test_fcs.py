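import numpy as np
import pytest

from ccakit.correlator import CorrelationCurve
from ccakit.detector import pinhole_configuration, summed_correlation_theory
from ccakit.fcs import (
    GAMMA_3D_GAUSSIAN,
    BrightnessModel,
    apparent_brightness,
    brightness_analog,
    diffusion_model,
    estimate_detector_gain,
    fit_diffusion_model,
    number_from_amplitude,
)

A = 2.97


def model_curve(G0=0.05, tau_D=1e-3, noise=0.0, rng=None, mean_a=None):
    lags = np.geomspace(2e-6, 1.0, 200)
    vals = diffusion_model(lags, G0, tau_D, A)
    if noise:
        vals = vals + rng.normal(0, noise, lags.size)
    return CorrelationCurve(
        lags=lags,
        values=vals,
        stderr=np.full(lags.size, max(noise, 1e-4)),
        corrected=True,
        kind="auto",
        channel_spec=0,
        t_sample=2e-6,
        mean_a=mean_a,
    )


class TestDiffusionFit:
    def test_identity_fit_on_noiseless_model(self):
        fit = fit_diffusion_model(model_curve(), A)
        assert fit.G0 == pytest.approx(0.05, rel=1e-6)
        assert fit.tau_D == pytest.approx(1e-3, rel=1e-6)

    def test_model_limit_at_zero_lag_is_G0(self):
        assert diffusion_model(np.array([0.0]), 0.05, 1e-3, A)[0] == 0.05

    def test_fit_recovers_under_noise(self, rng):
        fit = fit_diffusion_model(model_curve(noise=5e-4, rng=rng), A)
        assert fit.tau_D == pytest.approx(1e-3, rel=0.1)

    def test_insufficient_lags_rejected(self):
        cur = model_curve()
        from ccakit.fcs import FitFailureError

        with pytest.raises(FitFailureError):
            fit_diffusion_model(cur, A, fit_range=(0.95, 1.0))

    def test_number_amplitude_product_is_gamma(self):
        fit = fit_diffusion_model(model_curve(), A)
        assert fit.N * fit.G0 == pytest.approx(GAMMA_3D_GAUSSIAN, rel=1e-9)

    def test_tauD_scales_with_waist_squared_across_levels(self, array):
        # noiseless oracle curves from the exact summed-profile correlation
        D = 30.0
        taus, w2s = [], []
        for level in (1, 2, 3, 4):
            conf = pinhole_configuration(array, level)
            w = conf.effective_waist * 1e-3
            lags = np.geomspace(1e-6, 0.3, 300)
            g = summed_correlation_theory(array, conf.member_indices, lags, D)
            cur = CorrelationCurve(
                lags=lags, values=g / g[0] * 0.1,
                stderr=np.full(lags.size, 1e-4), corrected=True,
                kind="auto", channel_spec=0, t_sample=1e-6,
            )
            fit = fit_diffusion_model(cur, A)
            taus.append(fit.tau_D)
            w2s.append(conf.effective_waist**2)
        r = np.corrcoef(w2s, taus)[0, 1]
        assert r > 0.98
        # level-1 is a true Gaussian: tau_D = w^2/(4D) exactly
        assert taus[0] == pytest.approx((144e-3) ** 2 / (4 * D), rel=0.02)


class TestNumberAndBrightness:
    def test_number_from_equal_amplitude(self):
        assert number_from_amplitude(0.3536, gamma=0.3536) == 1.0

    def test_number_hand_value(self):
        assert number_from_amplitude(0.03536, gamma=0.3536) == pytest.approx(10.0)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            number_from_amplitude(0.0)

    def test_brightness_hand_value(self):
        # 100 counts * 0.01 / 2.46 us = 4.065e5 counts/s
        assert brightness_analog(100, 0.01, 2.46e-6) == pytest.approx(4.065e5, rel=1e-3)

    def test_brightness_zero_amplitude(self):
        assert brightness_analog(100, 0.0, 2.46e-6) == 0.0

    def test_brightness_requires_positive_sampling(self):
        with pytest.raises(ValueError):
            brightness_analog(100, 0.01, 0.0)

    def test_gain_scales_brightness_not_amplitude(self, rng):
        # doubling the detector gain doubles B_analog but leaves G0 unchanged
        fit1 = fit_diffusion_model(model_curve(mean_a=100.0), A)
        fit2 = fit_diffusion_model(model_curve(mean_a=200.0), A)
        assert fit2.G0 == pytest.approx(fit1.G0, rel=1e-9)
        assert fit2.B_analog == pytest.approx(2 * fit1.B_analog, rel=1e-9)

    def test_apparent_brightness_identity_gain(self):
        assert apparent_brightness(5e4, BrightnessModel(S_detector=1.0)) == 5e4

    def test_uncalibrated_gain_rejected(self):
        with pytest.raises(ValueError):
            BrightnessModel(S_detector=0.0)

    def test_detector_gain_from_poisson_reference(self, rng):
        gain, offset = 7.0, 100.0
        photons = rng.poisson(4.0, 2**16)
        trace = gain * photons + offset + rng.normal(0, 2.0, photons.size)
        model = estimate_detector_gain(trace, dark_mean=offset, dark_var=4.0)
        assert model.S_detector == pytest.approx(gain, rel=0.05)
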