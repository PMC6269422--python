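import numpy as np
import pytest

from ccakit.detector import (
    DetectorArray,
    InvalidParameterError,
    build_airyscan_layout,
    config_effective_volume,
    effective_volume,
    effective_waist_of_sum,
    pinhole_configuration,
    ring_members,
    summed_correlation_theory,
)


class TestLayout:
    def test_ring_populations(self, array):
        assert array.n_detectors == 32
        assert [len(ring_members(array, r)) for r in range(4)] == [1, 6, 12, 13]

    def test_center_at_origin(self, array):
        assert np.allclose(array.positions[0], 0.0)

    def test_ring1_at_pitch(self, array):
        r = array.radii[ring_members(array, 1)]
        assert np.allclose(r, array.pitch)

    def test_ring2_distances(self, array):
        r = np.sort(array.radii[ring_members(array, 2)])
        assert np.allclose(r[:6], np.sqrt(3) * array.pitch)
        assert np.allclose(r[6:], 2 * array.pitch)

    def test_waists_nondecreasing_with_radius(self, array):
        order = np.argsort(array.radii)
        assert np.all(np.diff(array.waists[order]) >= -1e-12)

    def test_zero_slope_gives_constant_waists(self):
        arr = build_airyscan_layout(waist_slope=0.0)
        assert np.allclose(arr.waists, arr.waists[0])

    def test_positions_reproducible_bit_identical(self):
        a = build_airyscan_layout()
        b = build_airyscan_layout()
        assert a.positions.tobytes() == b.positions.tobytes()
        assert a.waists.tobytes() == b.waists.tobytes()

    def test_json_round_trip(self, array):
        back = DetectorArray.from_json(array.to_json())
        assert np.allclose(back.positions, array.positions)
        assert np.allclose(back.waists, array.waists)

    @pytest.mark.parametrize("kwargs", [{"pitch": 0}, {"pitch": -1}, {"w0": 0}])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            build_airyscan_layout(**kwargs)

    def test_unknown_ring_rejected(self, array):
        with pytest.raises(InvalidParameterError):
            ring_members(array, 4)


class TestPinholes:
    def test_nested_member_sets(self, array):
        confs = [pinhole_configuration(array, lv) for lv in (1, 2, 3, 4)]
        for small, big in zip(confs, confs[1:]):
            assert set(small.member_indices) < set(big.member_indices)

    def test_waists_increase_within_calibrated_span(self, array):
        w = [pinhole_configuration(array, lv).effective_waist for lv in (1, 2, 3, 4)]
        assert np.all(np.diff(w) > 0)
        assert w[0] == pytest.approx(144.0, abs=0.5)
        assert w[-1] == pytest.approx(196.0, abs=0.5)

    def test_volumes_strictly_increasing(self, array):
        v = [pinhole_configuration(array, lv).effective_volume for lv in (1, 2, 3, 4)]
        assert np.all(np.diff(v) > 0)

    def test_level_out_of_range(self, array):
        with pytest.raises(InvalidParameterError):
            pinhole_configuration(array, 5)

    def test_single_member_profile_waist_is_member_waist(self, array):
        w = effective_waist_of_sum(array, [0], grid_step=2.0)
        assert w == pytest.approx(array.waists[0], rel=1e-3)

    def test_profile_fit_waists_increase(self, array):
        w = [
            effective_waist_of_sum(array, range(n), grid_step=2.0)
            for n in (1, 7, 13, 19)
        ]
        assert np.all(np.diff(w) > 0)

    def test_exact_volume_matches_closed_form_for_single_gaussian(self, array):
        v = config_effective_volume(array, [0])
        assert v == pytest.approx(
            effective_volume(array.waists[0] * 1e-3, array.aspect_ratio), rel=1e-12
        )

    def test_exact_volume_below_gaussian_formula_for_sums(self, array):
        # a flat-topped superposition has less effective volume than a
        # Gaussian at the fitted waist
        conf = pinhole_configuration(array, 4)
        gauss = effective_volume(conf.effective_waist * 1e-3, array.aspect_ratio)
        assert conf.effective_volume < gauss

    def test_summed_correlation_single_member_is_standard_model(self, array):
        w = array.waists[0] * 1e-3
        A = array.aspect_ratio
        tau_d = w**2 / 4.0
        lags = np.geomspace(tau_d / 100, tau_d * 100, 50)
        g = summed_correlation_theory(array, [0], lags, D=1.0)
        model = 1.0 / ((1 + lags / tau_d) * np.sqrt(1 + lags / (A * A * tau_d)))
        assert np.allclose(g / g[0], model / model[0], rtol=1e-9)


class TestEffectiveVolume:
    def test_reference_value(self):
        # pi^1.5 * 0.196^3 * 2.97, evaluated independently
        assert effective_volume(0.196, 2.97) == pytest.approx(0.124523, rel=1e-4)

    def test_cubic_scaling(self):
        assert effective_volume(0.4, 3.0) == pytest.approx(
            8 * effective_volume(0.2, 3.0), rel=1e-12
        )

    def test_proportional_in_aspect_ratio(self):
        assert effective_volume(0.2, 1e-6) == pytest.approx(
            1e-6 * effective_volume(0.2, 1.0), rel=1e-9
        )

    @pytest.mark.parametrize("w,A", [(0, 1), (-1, 1), (0.2, 0), (0.2, -2)])
    def test_invalid_inputs(self, w, A):
        with pytest.raises(InvalidParameterError):
            effective_volume(w, A)
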