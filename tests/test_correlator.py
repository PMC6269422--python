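import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccakit.correlator import (
    DarkCalibration,
    MultiTauScheme,
    SignalBelowDarkError,
    TimeTrace,
    ZeroMeanChannelError,
    autocorrelate_direct,
    autocorrelate_multitau,
    characterize_dark,
    correct_analog,
    crosscorrelate_multitau,
    sum_channels,
)

TS = 1e-5


def poisson_trace(rng, T=2**14, lam=5.0, C=1):
    return TimeTrace(rng.poisson(lam, (T, C)).astype(float), TS)


class TestEstimators:
    def test_constant_trace_is_uncorrelated(self):
        tr = TimeTrace(np.full(4096, 3.0), TS)
        assert np.all(autocorrelate_multitau(tr).values == 0)
        assert np.all(autocorrelate_direct(tr).values == 0)

    def test_iid_noise_decorrelates(self, rng):
        tr = poisson_trace(rng)
        cur = autocorrelate_multitau(tr)
        ok = np.abs(cur.values) <= 3 * cur.stderr
        assert ok.mean() > 0.9
        assert abs(cur.values.mean()) < 1e-3

    def test_sinusoid_correlation_is_cosine(self):
        P = 200
        t = np.arange(2**14)
        tr = TimeTrace(np.sin(2 * np.pi * t / P) + 2.0, TS)
        cur = autocorrelate_direct(tr, max_lag=300)
        # closed form: G(tau) proportional to cos(2 pi tau / P); first zero
        # crossing at tau = P/4
        first_neg = int(np.argmax(cur.values < 0))
        assert abs(first_neg - P // 4) <= 2
        k = np.arange(1, 301)
        expected = np.cos(2 * np.pi * k / P)
        r = np.corrcoef(cur.values, expected)[0, 1]
        assert r > 0.999

    def test_multitau_cascade0_matches_direct_oracle(self, rng):
        tr = poisson_trace(rng, T=2**16)
        d = autocorrelate_direct(tr)
        m = autocorrelate_multitau(tr)
        n = MultiTauScheme().points_per_cascade
        rel = np.abs(m.values[:n] - d.values[:n]) / np.maximum(
            np.abs(d.values[:n]), 1e-300
        )
        assert rel.max() < 1e-10

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_cascade0_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2**10, 2**13))
        x = rng.poisson(3.0, T).astype(float) + rng.normal(0, 0.3, T)
        x -= min(0.0, x.min()) - 1.0
        tr = TimeTrace(x, TS)
        d = autocorrelate_direct(tr)
        m = autocorrelate_multitau(tr)
        n = min(MultiTauScheme().points_per_cascade, d.values.size, m.values.size)
        assert np.allclose(m.values[:n], d.values[:n], rtol=1e-10, atol=1e-300)

    @pytest.mark.parametrize("gain", [0.1, 7.3, 1000.0])
    def test_gain_invariance(self, rng, gain):
        """A constant gain cancels exactly in G = <dI dI>/<I>^2.

        Pointwise relative comparison, floored at 0.1% of the curve peak:
        relative error is ill-defined where G itself crosses zero.
        """
        tr = poisson_trace(rng)
        base = autocorrelate_multitau(tr).values
        scaled = autocorrelate_multitau(TimeTrace(gain * tr.values, TS)).values
        floor = 1e-3 * np.abs(base).max()
        rel = np.abs(scaled - base) / np.maximum(np.abs(base), floor)
        assert rel.max() < 1e-12

    def test_zero_mean_channel_raises(self):
        tr = TimeTrace(np.zeros(4096), TS)
        with pytest.raises(ZeroMeanChannelError):
            autocorrelate_multitau(tr)

    def test_lags_start_at_sampling_time(self, rng):
        cur = autocorrelate_multitau(poisson_trace(rng))
        assert cur.lags[0] == pytest.approx(TS)
        assert np.all(np.diff(cur.lags) > 0)


class TestCrossCorrelation:
    def test_self_cross_equals_auto(self, rng):
        tr = poisson_trace(rng, C=2)
        auto = autocorrelate_multitau(tr, 0)
        cross = crosscorrelate_multitau(tr, 0, 0)
        assert np.allclose(auto.values, cross.values, rtol=1e-12)

    def test_independent_channels_uncorrelated(self, rng):
        tr = poisson_trace(rng, T=2**15, C=2)
        cur = crosscorrelate_multitau(tr, 0, 1)
        assert (np.abs(cur.values) <= 3 * cur.stderr).mean() > 0.9

    def test_time_reversal_symmetry(self, rng):
        tr = poisson_trace(rng, T=2**13, C=2)
        rev = TimeTrace(tr.values[::-1].copy(), TS)
        ab = crosscorrelate_multitau(tr, 0, 1)
        ba_rev = crosscorrelate_multitau(rev, 1, 0)
        # G_ab(tau) on the trace equals G_ba(tau) on the time-reversed trace
        assert np.allclose(ab.values, ba_rev.values, rtol=1e-9, atol=1e-12)


class TestSumChannels:
    def test_single_index_identity(self, rng):
        tr = poisson_trace(rng, C=3)
        s = sum_channels(tr, [1])
        assert np.array_equal(s.values[:, 0], tr.values[:, 1])

    def test_constant_channels_add(self):
        tr = TimeTrace(np.column_stack([np.full(64, 2.0), np.full(64, 5.0)]), TS)
        assert np.all(sum_channels(tr, [0, 1]).values == 7.0)

    def test_variance_of_independent_sum(self, rng):
        tr = poisson_trace(rng, T=2**15, C=4, lam=6.0)
        s = sum_channels(tr, [0, 1, 2, 3])
        v_sum = s.values.var()
        v_parts = tr.values.var(axis=0).sum()
        assert v_sum == pytest.approx(v_parts, rel=0.05)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            sum_channels(poisson_trace(rng), [])

    def test_channel_map_resolution(self, rng):
        vals = rng.poisson(5.0, (4096, 2)).astype(float)
        tr = TimeTrace(vals, TS, {"channels": [7, 12]})
        assert np.array_equal(tr.channel(12), vals[:, 1])
        with pytest.raises(KeyError):
            tr.channel(3)


class TestDarkCorrection:
    def test_all_zero_dark(self):
        dark = TimeTrace(np.zeros((20000, 1)), TS)
        cal = characterize_dark(dark)
        assert cal.mean_offsets[0] == 0
        assert cal.is_zero

    def test_constant_offset_dark(self):
        dark = TimeTrace(np.full((20000, 1), 7.0), TS)
        cal = characterize_dark(dark)
        assert cal.mean_offsets[0] == 7.0
        lags, num = cal.numerators(0)
        assert np.allclose(num, 0.0)

    def test_white_noise_dark_numerators_vanish_at_positive_lags(self, rng):
        v = 16.0
        dark = TimeTrace(200 + rng.normal(0, np.sqrt(v), (2**16, 1)), TS)
        cal = characterize_dark(dark)
        lags, num = cal.numerators(0)
        # white noise: covariance numerator ~ 0 for tau >= one sample
        assert np.abs(num).max() < 5 * v / np.sqrt(2**16)
        assert cal.mean_offsets[0] == pytest.approx(200, abs=0.1)

    def test_short_dark_warns(self, rng):
        with pytest.warns(UserWarning):
            characterize_dark(TimeTrace(rng.normal(10, 1, (2048, 1)), TS))

    def test_zero_dark_correction_is_identity(self, rng):
        tr = poisson_trace(rng)
        raw = autocorrelate_multitau(tr)
        cal = DarkCalibration.zeros_like(tr)
        cor = correct_analog(raw, cal)
        assert np.array_equal(cor.values, raw.values)
        assert cor.corrected

    def test_gain_scaling_leaves_corrected_curve_unchanged(self, rng):
        x = rng.poisson(5.0, 2**14).astype(float)
        dark_vals = 50 + rng.normal(0, 2, 2**14)
        for A in (1.0, 3.7):
            sig = TimeTrace(A * (x + dark_vals), TS)
            cal = characterize_dark(TimeTrace(A * dark_vals.copy(), TS))
            cor = correct_analog(autocorrelate_multitau(sig), cal)
            if A == 1.0:
                base = cor.values
        assert np.allclose(cor.values, base, rtol=1e-9)

    def test_offset_and_dark_noise_are_removed(self, rng):
        # AR(1) signal + offset process: corrected amplitude matches the
        # clean signal's amplitude; the raw amplitude does not
        T = 2**17
        phi = 0.995
        e = rng.normal(size=T)
        s = np.empty(T)
        s[0] = 0.0
        for t in range(1, T):
            s[t] = phi * s[t - 1] + e[t]
        clean = 50 + 5 * s
        offset = 200 + rng.normal(0, 20, T)
        dark = 200 + rng.normal(0, 20, T)
        raw = autocorrelate_multitau(TimeTrace(clean + offset, TS))
        cal = characterize_dark(TimeTrace(dark, TS))
        cor = correct_analog(raw, cal)
        ref = autocorrelate_multitau(TimeTrace(clean, TS))
        assert cor.values[0] == pytest.approx(ref.values[0], rel=0.05)
        assert abs(raw.values[0] - ref.values[0]) / ref.values[0] > 0.5

    def test_signal_below_dark_rejected(self, rng):
        sig = TimeTrace(rng.poisson(5.0, 2**14).astype(float), TS)
        cal = characterize_dark(TimeTrace(np.full((2**14, 1), 100.0), TS))
        with pytest.raises(SignalBelowDarkError):
            correct_analog(autocorrelate_multitau(sig), cal)
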