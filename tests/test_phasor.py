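import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splitpin import (
    CalibrationError,
    PhasorCalibration,
    StackValidationError,
    auto_calibrate,
    component_fraction,
    decompose,
    logistic_filter,
    phasor_transform,
    profile_phasor,
    smooth_phasor,
    split_pin_image,
    subtractive_baseline,
)
from conftest import stack_from_profiles


def field_of_profiles(profiles):
    """Phasor field of a stack whose pixels carry the given 3-profiles."""
    profiles = np.asarray(profiles, dtype=float)  # (npix, 3)
    frames = profiles.T.reshape(3, -1, 1)
    return phasor_transform(stack_from_profiles(frames))


class TestPhasorTransform:
    @pytest.mark.parametrize("profile, expected", [
        ((5.0, 5.0, 5.0), (0.0, 0.0)),       # roots of unity sum to zero
        ((1.0, 0.0, 0.0), (1.0, 0.0)),       # all mass at j=1
        ((0.0, 1.0, 0.0), (-0.5, np.sin(2 * np.pi / 3))),
        ((0.0, 0.0, 1.0), (-0.5, -np.sin(2 * np.pi / 3))),
    ])
    def test_known_profiles(self, profile, expected):
        field = field_of_profiles([profile])
        assert field.g[0, 0] == pytest.approx(expected[0], abs=1e-12)
        assert field.s_coord[0, 0] == pytest.approx(expected[1], abs=1e-12)

    def test_delta_profile_polar_coordinates(self):
        field = field_of_profiles([(1.0, 0.0, 0.0)])
        assert field.M[0, 0] == pytest.approx(1.0)
        assert field.phi[0, 0] == pytest.approx(0.0)

    def test_zero_total_pixel_flagged(self):
        field = field_of_profiles([(0.0, 0.0, 0.0), (1.0, 2.0, 3.0)])
        assert field.undefined[0, 0]
        assert not field.undefined[1, 0]
        assert field.g[0, 0] == 0.0 and field.s_coord[0, 0] == 0.0

    def test_all_zero_stack_warns_and_flags(self, caplog):
        frames = np.zeros((3, 4, 4))
        with caplog.at_level("WARNING"):
            field = phasor_transform(stack_from_profiles(frames))
        assert field.undefined.all()
        assert any("zero total" in r.message for r in caplog.records)

    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=6).filter(
        lambda p: sum(p) > 0))
    @settings(max_examples=200, deadline=None)
    def test_modulation_within_unit_circle(self, profile):
        g, s = profile_phasor(profile)
        assert np.hypot(g, s) <= 1.0 + 1e-12

    def test_mixture_linearity_on_random_profiles(self, rng):
        # phasor of a*A + b*B sits on the segment joining the component
        # phasors at the intensity fraction of A
        for _ in range(100):
            prof_a = rng.random(3) + 1e-3
            prof_b = rng.random(3) + 1e-3
            a, b = rng.random(2) + 1e-3
            pa = np.array(profile_phasor(prof_a))
            pb = np.array(profile_phasor(prof_b))
            pm = np.array(profile_phasor(a * prof_a + b * prof_b))
            frac = a * prof_a.sum() / (a * prof_a.sum() + b * prof_b.sum())
            np.testing.assert_allclose(pm, frac * pa + (1 - frac) * pb,
                                       atol=1e-12)


class TestComponentFraction:
    def test_projection_endpoints_and_midpoint(self, default_calibration):
        p_in = np.array(default_calibration.p_in)
        p_out = np.array(default_calibration.p_out)
        mid = (p_in + p_out) / 2
        field = field_of_profiles([(1.0, 1.0, 1.0)] * 3)
        field.g = np.array([[p_in[0]], [p_out[0]], [mid[0]]])
        field.s_coord = np.array([[p_in[1]], [p_out[1]], [mid[1]]])
        field.undefined = np.zeros((3, 1), dtype=bool)
        f = component_fraction(field, default_calibration)
        np.testing.assert_allclose(f[:, 0], [1.0, 0.0, 0.5], atol=1e-12)

    def test_off_segment_component_is_ignored(self, default_calibration):
        # (0.30, 0.25) projects onto the segment midpoint: the orthogonal
        # offset does not change the fraction
        field = field_of_profiles([(1.0, 1.0, 1.0)])
        field.g = np.array([[0.30]])
        field.s_coord = np.array([[0.25]])
        field.undefined = np.zeros((1, 1), dtype=bool)
        f = component_fraction(field, default_calibration)
        assert f[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_coincident_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            PhasorCalibration((0.3, 0.2), (0.3, 0.2))

    def test_two_component_intensity_fraction_recovered(self, rng):
        # noiseless mixtures of known IN/OUT profiles: the projection is
        # the true in-focus intensity fraction, before any filtering
        prof_in = np.array([1.4, 1.0, 0.38])
        prof_out = np.array([1.4, 1.0, 0.38]) * np.exp(
            -2 * 500.0**2 / np.array([680.0, 620.0, 590.0]) ** 2)
        calib = PhasorCalibration(profile_phasor(prof_in),
                                  profile_phasor(prof_out))
        a = rng.random((8, 8)) + 0.01
        b = rng.random((8, 8)) + 0.01
        frames = (a[None] * prof_in[:, None, None]
                  + b[None] * prof_out[:, None, None])
        stack = stack_from_profiles(frames)
        f_raw = component_fraction(phasor_transform(stack), calib)
        truth = a * prof_in.sum() / (a * prof_in.sum() + b * prof_out.sum())
        np.testing.assert_allclose(f_raw, truth, atol=1e-10)

    def test_wild_fractions_trigger_diagnostic(self, default_calibration):
        field = field_of_profiles([(1.0, 0.0, 0.0)])  # phasor (1, 0)
        with pytest.warns(UserWarning, match="extreme raw fractions"):
            component_fraction(field, default_calibration)


class TestLogisticFilter:
    def test_midpoint_fixed_point(self):
        assert logistic_filter(np.array([0.5]))[0] == pytest.approx(0.5)

    def test_endpoint_value_at_default_steepness(self):
        f = logistic_filter(np.array([1.0]), k_L=4.0)
        assert f[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)
        assert f[0] == pytest.approx(0.88080, abs=1e-5)

    # ranges kept where float64 cannot saturate the exponential
    @given(st.floats(-4, 5), st.floats(0.1, 4.5))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, x, k):
        lo = logistic_filter(np.array([x]), k_L=k)[0]
        hi = logistic_filter(np.array([x + 1.0]), k_L=k)[0]
        assert 0.0 < lo < 1.0
        assert hi > lo

    def test_saturates_within_unit_interval_for_extreme_inputs(self):
        f = logistic_filter(np.array([-1e6, 1e6]), k_L=4.0)
        assert f[0] >= 0.0 and f[1] <= 1.0


class TestSplitImage:
    def test_unit_fraction_returns_conf_image(self, noiseless_stack):
        stack, _ = noiseless_stack
        f = np.ones(stack.shape)
        res = split_pin_image(stack, f, "sum")
        np.testing.assert_allclose(res.split_image.pixels,
                                   stack.frames.sum(axis=0))

    def test_constant_fraction_scales_conf(self):
        frames = np.stack([np.full((4, 4), v) for v in (4.0, 3.0, 3.0)])
        stack = stack_from_profiles(frames)
        res = split_pin_image(stack, np.full((4, 4), 0.5), [2])
        np.testing.assert_allclose(res.split_image.pixels, 1.5)

    @pytest.mark.parametrize("selection, frames", [
        ("last", (2,)), ("2-3", (1, 2)), ("1-3", (0, 1, 2)),
        ("sum", (0, 1, 2)),
    ])
    def test_named_variants_select_frames(self, noiseless_stack, selection,
                                          frames):
        stack, _ = noiseless_stack
        res = split_pin_image(stack, np.ones(stack.shape), selection)
        assert res.conf_selection == frames

    def test_empty_selection_rejected(self, noiseless_stack):
        stack, _ = noiseless_stack
        with pytest.raises(StackValidationError):
            split_pin_image(stack, np.ones(stack.shape), [])

    def test_shape_mismatch_rejected(self, noiseless_stack):
        stack, _ = noiseless_stack
        with pytest.raises(StackValidationError):
            split_pin_image(stack, np.ones((3, 3)), "sum")

    def test_noiseless_single_emitter_peak_composition(self,
                                                       default_calibration):
        # peak of the synthesised image is f_in(peak) * (1.4+1+0.38) * S
        from splitpin import EmitterField, SimulationConfig, simulate_stack

        cfg = SimulationConfig(n_emitters=1, S=100.0, noise="none")
        em = EmitterField(np.array([[128, 128]]), np.ones(1), cfg.grid)
        stack, _ = simulate_stack(cfg, emitters=em)
        res = decompose(stack, default_calibration, "1-3", smooth=0)
        expected = res.f_in[128, 128] * 2.78 * 100.0
        assert res.split_image.pixels[128, 128] == pytest.approx(expected)

    def test_dark_pixels_stay_dark(self, default_calibration):
        frames = np.zeros((3, 4, 4))
        frames[:, 1, 1] = (1.4, 1.0, 0.38)
        stack = stack_from_profiles(frames)
        res = decompose(stack, default_calibration, "sum", smooth=0)
        assert res.split_image.pixels[0, 0] == 0.0
        assert res.f_in[0, 0] == 0.0
        assert res.split_image.pixels[1, 1] > 0


class TestSmoothing:
    def test_median_window_removes_salt_noise_in_phasor_maps(self):
        frames = np.ones((3, 16, 16)) * np.array([1.4, 1.0, 0.38])[:, None, None]
        frames[:, 8, 8] = (0.0, 0.0, 5.0)  # one aberrant pixel
        field = phasor_transform(stack_from_profiles(frames))
        smoothed = smooth_phasor(field, size=3)
        ref = field.g[0, 0]
        assert abs(field.g[8, 8] - ref) > 0.1
        assert smoothed.g[8, 8] == pytest.approx(ref, abs=1e-12)

    def test_size_below_two_is_identity(self):
        frames = np.random.default_rng(0).random((3, 8, 8))
        field = phasor_transform(stack_from_profiles(frames))
        assert smooth_phasor(field, size=0) is field


class TestAutoCalibrate:
    def test_recovers_pure_component_phasors(self, rng):
        prof_in = np.array([1.4, 1.0, 0.38])
        prof_out = prof_in * np.exp(
            -2 * 500.0**2 / np.array([680.0, 620.0, 590.0]) ** 2)
        n = 500
        pure = np.where(rng.random(n) < 0.5, 0, 1)
        profiles = np.where(pure[:, None], prof_in, prof_out)
        profiles = profiles * (0.5 + rng.random((n, 1)))
        frames = profiles.T.reshape(3, -1, 1)
        field = phasor_transform(stack_from_profiles(frames))
        calib = auto_calibrate(field, percentiles=(1, 99))
        np.testing.assert_allclose(calib.p_in, profile_phasor(prof_in),
                                   atol=0.01)
        np.testing.assert_allclose(calib.p_out, profile_phasor(prof_out),
                                   atol=0.01)

    def test_degenerate_distribution_rejected(self):
        frames = np.ones((3, 8, 8))
        field = phasor_transform(stack_from_profiles(frames))
        with pytest.raises(CalibrationError, match="degenerate|manually"):
            auto_calibrate(field)

    def test_simulation_defaults_produce_bracketed_cloud(self,
                                                         default_calibration):
        from splitpin import SimulationConfig, simulate_stack

        cfg = SimulationConfig(S=500.0, seed=4)
        stack, _ = simulate_stack(cfg)
        field = smooth_phasor(phasor_transform(stack), 3)
        calib = auto_calibrate(field, intensity_threshold=50.0)
        seg = np.array(default_calibration.p_out) - np.array(
            default_calibration.p_in)
        proposed = (np.array(calib.p_out) - np.array(calib.p_in))
        # proposal spans the same axis direction as the reference points
        cos = proposed @ seg / np.linalg.norm(proposed) / np.linalg.norm(seg)
        assert abs(cos) > 0.9


class TestSubtractiveBaseline:
    def test_zero_gamma_returns_smallest_pinhole_frame(self, noiseless_stack):
        stack, _ = noiseless_stack
        out = subtractive_baseline(stack, gamma=0.0)
        np.testing.assert_array_equal(out.pixels, stack.frames[-1])

    def test_identical_frames_unchanged(self):
        frames = np.ones((2, 4, 4)) * 7
        stack = stack_from_profiles(frames, sizes=(1.5, 0.5))
        out = subtractive_baseline(stack, gamma=0.15)
        np.testing.assert_allclose(out.pixels, 7.0)

    def test_weighted_subtraction_arithmetic(self):
        ph2 = np.full((4, 4), 10.0)
        frames = np.stack([2 * ph2, ph2])
        stack = stack_from_profiles(frames, sizes=(1.5, 0.5))
        out = subtractive_baseline(stack, gamma=0.15)
        np.testing.assert_allclose(out.pixels, 8.5)

    def test_negative_gamma_rejected(self, noiseless_stack):
        stack, _ = noiseless_stack
        with pytest.raises(StackValidationError):
            subtractive_baseline(stack, gamma=-0.1)

    def test_negatives_clamped(self):
        frames = np.stack([np.full((2, 2), 100.0), np.full((2, 2), 1.0)])
        stack = stack_from_profiles(frames, sizes=(1.5, 0.5))
        out = subtractive_baseline(stack, gamma=0.5)
        assert np.all(out.pixels >= 0)
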