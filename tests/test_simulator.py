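import numpy as np
import pytest

from ccakit.correlator import characterize_dark
from ccakit.simulate import (
    AnalogModel,
    EnvironmentSpec,
    SimulationConfig,
    render_detector_trace,
    simulate_dark_trace,
    simulate_trace,
    simulate_trajectories,
)


def small_config(**kw):
    base = dict(n_steps=20_000, n_particles=50, channels=(0,), seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestTrajectories:
    def test_seed_determinism_bit_identical(self):
        a = simulate_trajectories(small_config())
        b = simulate_trajectories(small_config())
        assert a.tobytes() == b.tobytes()

    def test_different_seeds_differ(self):
        a = simulate_trajectories(small_config())
        b = simulate_trajectories(small_config(seed=12))
        assert not np.array_equal(a, b)

    def test_per_step_variance_matches_einstein_relation(self):
        cfg = SimulationConfig(n_steps=100_000, n_particles=100, channels=(0,), seed=3)
        paths = simulate_trajectories(cfg)
        d = np.diff(paths, axis=0)
        box = np.array(cfg.box)
        d -= box * np.round(d / box)  # undo periodic wraps
        assert d.var() == pytest.approx(2 * cfg.D * cfg.t_sample, rel=0.02)

    def test_zero_diffusion_is_static(self):
        paths = simulate_trajectories(small_config(D=0.0))
        assert np.all(paths[0] == paths[-1])

    def test_excluded_sphere_never_entered(self):
        env = EnvironmentSpec.excluded_sphere(radius=0.12)
        paths = simulate_trajectories(small_config(environment=env))
        r2 = (paths**2).sum(axis=2)
        assert r2.min() >= 0.12**2 - 1e-12

    def test_barrier_slab_never_entered(self):
        env = EnvironmentSpec.barrier(x0=0.025, thickness=0.05)
        paths = simulate_trajectories(small_config(environment=env))
        x = paths[..., 0]
        assert not np.any((x > 0.0) & (x < 0.05))

    def test_stability_warning_for_coarse_steps(self):
        env = EnvironmentSpec.excluded_sphere(radius=0.012)
        with pytest.warns(UserWarning):
            simulate_trajectories(small_config(environment=env))


class TestRendering:
    def test_static_centered_particle_mean_intensity(self):
        cfg = SimulationConfig(
            D=0.0, n_particles=1, channels=(0,), n_steps=20_000, seed=5,
            brightness=0.5, analog=AnalogModel(gain=4, offset=200, dark_sigma=0),
        )
        paths = np.zeros((cfg.n_steps, 1, 3))
        analog, photons = render_detector_trace(paths, cfg)
        # expected photons/timepoint at the PSF center = brightness
        assert photons.values.mean() == pytest.approx(0.5, rel=0.05)
        assert analog.values.mean() == pytest.approx(4 * 0.5 + 200, rel=0.01)

    def test_zero_brightness_gives_pure_dark_record(self):
        cfg = small_config(brightness=0.0)
        analog, photons = simulate_trace(cfg)
        assert np.all(photons.values == 0)
        assert analog.values.std() == pytest.approx(
            cfg.analog.dark_sigma, rel=0.05
        )

    def test_trace_seed_determinism(self):
        a, _ = simulate_trace(small_config())
        b, _ = simulate_trace(small_config())
        assert a.values.tobytes() == b.values.tobytes()

    def test_gain_change_preserves_correlation_amplitude(self):
        from ccakit.correlator import autocorrelate_multitau

        cfg1 = small_config(n_steps=100_000, analog=AnalogModel(750, 0, 0))
        cfg2 = small_config(n_steps=100_000, analog=AnalogModel(1500, 0, 0))
        a1, _ = simulate_trace(cfg1)
        a2, _ = simulate_trace(cfg2)
        g1 = autocorrelate_multitau(a1).values
        g2 = autocorrelate_multitau(a2).values
        assert np.allclose(g1, g2, rtol=1e-9)

    def test_channel_subset_metadata(self):
        analog, _ = simulate_trace(small_config(channels=(7, 12)))
        assert analog.metadata["channels"] == [7, 12]
        assert analog.channel_count == 2


class TestTransport:
    def test_cross_correlation_peak_is_delayed_beyond_the_psf(self):
        """Two detectors separated beyond their waists see the same molecule
        only after it diffuses across, so the cross-correlation peaks at a
        positive lag on the order of d^2/(4D)."""
        from ccakit.correlator import crosscorrelate_multitau
        from ccakit.detector import build_airyscan_layout

        arr = build_airyscan_layout(pitch=100.0, w0=50.0, waist_slope=0.0)
        cfg = SimulationConfig(
            n_steps=250_000, channels=(0, 1), seed=8, detector=arr,
            brightness=1.0,
        )
        _, photons = simulate_trace(cfg)
        cur = crosscorrelate_multitau(photons, 0, 1)
        i = int(np.argmax(cur.values))
        transit = (0.1**2) / (4 * cfg.D)
        assert cur.lags[i] > 3 * cfg.t_sample
        assert transit / 5 < cur.lags[i] < transit * 5
        assert cur.values[i] > 1.5 * cur.values[0]


class TestDarkTrace:
    def test_no_noise_dark_is_constant_offset(self):
        cfg = small_config(analog=AnalogModel(gain=750, offset=150, dark_sigma=0))
        dark = simulate_dark_trace(cfg)
        assert np.all(dark.values == 150.0)

    def test_zero_offset_zero_noise_is_all_zeros(self):
        cfg = small_config(analog=AnalogModel(gain=750, offset=0, dark_sigma=0))
        assert not np.any(simulate_dark_trace(cfg).values)

    def test_characterization_recovers_offset(self):
        cfg = small_config(analog=AnalogModel(gain=750, offset=200, dark_sigma=20))
        dark = simulate_dark_trace(cfg, n_steps=1_000_000)
        cal = characterize_dark(dark)
        assert cal.mean_offsets[0] == pytest.approx(200.0, rel=1e-3)


class TestValidation:
    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(box=(0.3, 1.0, 2.0))

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentSpec.microdomain(escape_prob=1.5)

    def test_unknown_environment_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentSpec("vortex")

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_particles=0)
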