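"""Degradation-trace pipeline and image quantification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fccskit.kinetics import (
    analyze_trace,
    bleach_correct_control,
    bleach_correct_linear,
    compartment_means,
    detect_onset,
    extract_line_profile,
    max_degradation_speed,
    minmax_scale,
    moving_average,
    normalize_trace,
    smooth_trace,
)
from fccskit.synthgen import degradation_closed_form, simulate_degradation_trace
from fccskit.types import DegradationTrace


def make_trace(frames, values, **kw):
    return DegradationTrace(np.asarray(frames), np.asarray(values, float), **kw)


def step_decay_trace(first=-20, last=0, plateau_end=-10, slope=0.1):
    """1.0 up to plateau_end, then decreasing `slope` per frame."""
    frames = np.arange(first, last + 1)
    values = np.where(frames <= plateau_end, 1.0,
                      1.0 - slope * (frames - plateau_end))
    return make_trace(frames, values)


class TestNormalize:
    def test_reference_frame_becomes_one(self):
        frames = np.arange(-25, 5)
        t = make_trace(frames, np.full(frames.size, 2.0))
        out = normalize_trace(t, reference_frame=-20)
        assert np.allclose(out.intensities, 1.0)
        assert out.intensities[out.index_of(-20)] == 1.0

    def test_background_subtracted_before_scaling(self):
        frames = np.arange(-25, 5)
        t = make_trace(frames, np.full(frames.size, 3.0), background=1.0)
        out = normalize_trace(t, reference_frame=-20)
        assert np.allclose(out.intensities, 1.0)

    def test_idempotent_on_normalised_trace(self):
        t = step_decay_trace()
        once = normalize_trace(t, reference_frame=-15)
        twice = normalize_trace(once, reference_frame=-15)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-15)

    def test_non_positive_reference_rejected(self):
        frames = np.arange(-25, 5)
        t = make_trace(frames, np.zeros(frames.size))
        with pytest.raises(ValueError):
            normalize_trace(t, reference_frame=-20)


class TestBleachCorrection:
    def test_control_self_correction_is_flat(self):
        t, _ = simulate_degradation_trace(decay_rate=0.0, noise_sd=0.0, seed=1)
        out = bleach_correct_control(t, t)
        assert np.allclose(out.intensities, 1.0, atol=1e-12)

    def test_unit_control_is_identity(self):
        t = step_decay_trace()
        control = make_trace(t.frames, np.ones(len(t.frames)))
        out = bleach_correct_control(t, control)
        assert np.array_equal(out.intensities, t.intensities)

    def test_control_division_recovers_decay_closed_form(self):
        kw = dict(baseline=1.0, bleach_rate=0.004, onset_frame=2,
                  noise_sd=0.0, frame_range=(-35, 35))
        t, _ = simulate_degradation_trace(decay_rate=0.08, seed=1, **kw)
        control, _ = simulate_degradation_trace(decay_rate=0.0, seed=1, **kw)
        out = bleach_correct_control(t, control)
        expected = degradation_closed_form(t.frames, 1.0, 0.0, 2, 0.08)
        assert np.allclose(out.intensities, expected, rtol=1e-9)

    def test_linear_correction_flattens_noiseless_control(self):
        t, _ = simulate_degradation_trace(
            bleach_rate=0.003, decay_rate=0.0, noise_sd=0.0, seed=1
        )
        out = bleach_correct_linear(t, fit_window=(-30, -25))
        assert np.allclose(out.intensities, 1.0, rtol=1e-9)

    def test_flat_trace_untouched_by_linear_correction(self):
        frames = np.arange(-35, 10)
        t = make_trace(frames, np.full(frames.size, 0.8))
        out = bleach_correct_linear(t)
        assert np.allclose(out.intensities, 1.0, atol=1e-12)

    def test_pre_onset_slope_removed_on_degrading_trace(self):
        t, _ = simulate_degradation_trace(
            bleach_rate=0.003, onset_frame=0, decay_rate=0.1, noise_sd=0.0,
            seed=1,
        )
        out = bleach_correct_linear(normalize_trace(t, -20))
        pre = out.intensities[(out.frames >= -20) & (out.frames <= -5)]
        slope = np.polyfit(np.arange(pre.size), pre, 1)[0]
        assert abs(slope) <= 1e-3

    def test_frame_mismatch_rejected(self):
        t = step_decay_trace(-20, 0)
        control = make_trace(np.arange(-19, 2), np.ones(21))
        with pytest.raises(ValueError):
            bleach_correct_control(t, control)


class TestSmoothing:
    def test_window_one_is_identity(self):
        vals = [3.0, 1.0, 4.0, 1.5]
        assert np.array_equal(moving_average(vals, 1), vals)

    def test_constant_input_unchanged(self):
        assert np.allclose(moving_average([2.0] * 10, 4), 2.0)

    def test_trailing_window_arithmetic(self):
        out = moving_average([1.0, 1.0, 1.0, 0.0], 4)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(0.75)

    def test_smooth_trace_keeps_trailing_frame_labels(self):
        t = step_decay_trace(-10, 0)
        s = smooth_trace(t, 4)
        assert s.frames[0] == -7
        assert s.frames[-1] == 0


class TestOnset:
    def test_hand_computed_worked_example(self):
        # plateau at 1.0 through frame -10, then -0.1/frame; with no
        # smoothing the windows starting at -13 and -12 have least-squares
        # slopes -0.02 and -0.05 (not strictly below the -0.05 threshold),
        # the window at -11 has slope -0.08 -> onset -11, speed -0.08
        t = step_decay_trace(-20, 0, plateau_end=-10, slope=0.1)
        onset, speed = detect_onset(t, smooth_window=1)
        assert onset == -11
        assert speed == pytest.approx(-0.08, abs=1e-12)

    def test_window_slopes_match_polyfit(self):
        t = step_decay_trace(-20, 0)
        smoothed = smooth_trace(t, 4)
        onset, speed = detect_onset(t, smooth_window=4)
        i = smoothed.index_of(onset)
        ref = np.polyfit(np.arange(5.0), smoothed.intensities[i : i + 5], 1)[0]
        assert speed == pytest.approx(ref, abs=1e-12)

    def test_flat_trace_has_no_onset(self):
        frames = np.arange(-30, 10)
        t = make_trace(frames, np.ones(frames.size))
        onset, speed = detect_onset(t)
        assert onset is None and speed is None

    def test_threshold_is_strict(self):
        # a slope exactly at the threshold must not trigger (strict <);
        # 1/16 is exactly representable so there is no rounding ambiguity
        frames = np.arange(-20, 0)
        t = make_trace(frames, 1.0 - 0.0625 * (frames - frames[0]))
        onset, _ = detect_onset(t, smooth_window=1, slope_threshold=-0.0625)
        assert onset is None
        onset, _ = detect_onset(t, smooth_window=1, slope_threshold=-0.0624)
        assert onset is not None

    def test_noisy_recovery_within_two_frames(self):
        hits = 0
        for seed in range(100):
            t, truth = simulate_degradation_trace(
                bleach_rate=0.002, onset_frame=0, decay_rate=0.1,
                noise_sd=0.02, seed=seed,
            )
            res = analyze_trace(t, reference_frame=-20, bleach_mode="linear")
            if res.onset_frame is not None and abs(res.onset_frame - 0) <= 2:
                hits += 1
        assert hits >= 90


class TestMaxSpeed:
    def test_globally_linear_trace_recovers_slope(self):
        frames = np.arange(-20, 10)
        t = make_trace(frames, 5.0 - 0.08 * (frames - frames[0]))
        speed, at = max_degradation_speed(t)
        assert speed == pytest.approx(-0.08, abs=1e-12)
        # constant derivative: tie broken to the earliest frame
        assert at == t.frames[4]

    def test_constant_trace_speed_zero(self):
        frames = np.arange(-20, 10)
        t = make_trace(frames, np.ones(frames.size))
        speed, _ = max_degradation_speed(t)
        assert speed == pytest.approx(0.0, abs=1e-12)

    def test_exponential_decay_matches_analytic_oracle(self):
        # oracle: the steepest 5-point least-squares chord of the smoothed
        # closed-form trace
        t, _ = simulate_degradation_trace(
            bleach_rate=0.0, onset_frame=0, decay_rate=0.1, noise_sd=0.0,
            frame_range=(-20, 40), seed=1,
        )
        smoothed = moving_average(t.intensities, 4)
        slopes = [
            np.polyfit(np.arange(5.0), smoothed[i : i + 5], 1)[0]
            for i in range(len(smoothed) - 4)
        ]
        oracle = min(slopes)
        speed, _ = max_degradation_speed(t, smooth_window=4)
        assert speed == pytest.approx(oracle, rel=0.10)


class TestScaleInvariance:
    @given(st.floats(1e-3, 1e4))
    def test_pipeline_invariant_to_intensity_scaling(self, c):
        t, _ = simulate_degradation_trace(
            bleach_rate=0.002, onset_frame=0, decay_rate=0.1, noise_sd=0.02,
            seed=11,
        )
        scaled = DegradationTrace(
            t.frames, t.intensities * c, 0.0, t.compartment,
            t.frame_interval, t.cell_id,
        )
        r1 = analyze_trace(t)
        r2 = analyze_trace(scaled)
        assert r1.onset_frame == r2.onset_frame
        assert r1.max_speed == pytest.approx(r2.max_speed, rel=1e-9)
        if r1.initial_speed is not None:
            assert r1.initial_speed == pytest.approx(r2.initial_speed, rel=1e-9)


class TestLineProfile:
    def test_constant_image_constant_profile(self):
        img = np.full((32, 32), 7.0)
        prof = extract_line_profile(img, (5, 16), (25, 16), thickness_px=10)
        assert np.allclose(prof.values["value"], 7.0, atol=1e-12)

    def test_axis_aligned_thickness_one_equals_pixel_row(self, rng):
        img = rng.integers(0, 100, (20, 30)).astype(float)
        prof = extract_line_profile(img, (3, 8), (12, 8), thickness_px=1)
        assert np.allclose(prof.values["value"], img[8, 3:13], atol=1e-12)

    def test_line_leaving_image_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            extract_line_profile(img, (1, 1), (40, 1))
        with pytest.raises(ValueError):
            extract_line_profile(img, (2, 2), (2, 2))


class TestMinMaxScale:
    def test_simple_example(self):
        assert np.allclose(minmax_scale([2, 4, 6]), [0.0, 0.5, 1.0])

    def test_attains_both_bounds_and_is_idempotent(self, rng):
        x = rng.normal(size=50)
        y = minmax_scale(x)
        assert y.min() == 0.0 and y.max() == 1.0
        assert np.allclose(minmax_scale(y), y, atol=1e-15)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            minmax_scale([3.0, 3.0, 3.0])


class TestCompartmentMeans:
    def test_constant_image_equal_means(self):
        img = np.full((10, 10), 4.0)
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        inside, outside = compartment_means(img, mask)
        assert inside == outside == 4.0

    def test_indicator_image(self):
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        img = mask * 5.0 + 1.0
        inside, outside = compartment_means(img, mask, background=1.0)
        assert inside == pytest.approx(5.0)
        assert outside == pytest.approx(0.0)

    def test_empty_or_full_mask_rejected(self):
        img = np.ones((4, 4))
        with pytest.raises(ValueError):
            compartment_means(img, np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            compartment_means(img, np.ones((4, 4), bool))
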