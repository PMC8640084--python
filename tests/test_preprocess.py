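"""Signal-conditioning oracles: alignment, resampling, filtering, trigger."""

import numpy as np
import pytest

import impactkit as ik
from impactkit.capture_model import CalibrationSet, accelerometer_stream, gyro_stream
from impactkit.preprocess import (
    SIGNAL_NAMES,
    TriageConfig,
    TriggerConfig,
    butterworth_lowpass,
    emulate_onboard_trigger,
    euclidean_norm,
    resample_to_common_rate,
)

from conftest import make_capture


def _steady_state_gain(freq: float, rate: float = 3200.0) -> float:
    """Measured steady-state amplitude ratio of the triage filter at freq."""
    t = np.arange(int(rate)) / rate
    out = butterworth_lowpass(np.sin(2 * np.pi * freq * t), rate)
    return float(np.abs(out[len(out) // 2 :]).max())


class TestAlignAxes:
    def test_identity_calibration_is_a_no_op(self):
        c = make_capture(amplitude=2.0)
        out = ik.align_axes(c, CalibrationSet.identity())
        for sid in c.streams:
            np.testing.assert_array_equal(
                out.streams[sid].samples, c.streams[sid].samples
            )

    def test_quarter_turn_about_z_maps_x_to_y(self):
        c = make_capture(n_acc=8, n_gyro=2)
        c.streams["left_acc"].samples[:] = 0.0
        c.streams["left_acc"].samples[0, :] = 1.0  # unit x
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        cal = CalibrationSet({sid: rz for sid in c.streams})
        out = ik.align_axes(c, cal)
        np.testing.assert_allclose(
            out.streams["left_acc"].samples[:, 0], [0.0, 1.0, 0.0], atol=1e-12
        )

    def test_random_rotation_preserves_per_sample_norms(self):
        from impactkit.synthetic_data import random_rotation

        rng = np.random.default_rng(5)
        c = make_capture(amplitude=3.0, seed=1)
        cal = CalibrationSet({sid: random_rotation(rng) for sid in c.streams})
        out = ik.align_axes(c, cal)
        for sid in c.streams:
            np.testing.assert_allclose(
                euclidean_norm(*out.streams[sid].samples),
                euclidean_norm(*c.streams[sid].samples),
                atol=1e-9,
            )

    def test_non_orthonormal_calibration_rejected(self):
        cal = CalibrationSet({sid: 2 * np.eye(3) for sid in ik.capture_model.SENSOR_IDS})
        with pytest.raises(ValueError, match="orthonormal"):
            ik.align_axes(make_capture(), cal)


class TestResampling:
    def test_stream_at_target_rate_passes_through(self):
        s = accelerometer_stream("left_acc", np.random.default_rng(0).normal(size=(3, 320)))
        out = resample_to_common_rate(s)
        np.testing.assert_array_equal(out.samples, s.samples)

    def test_gyro_upsampling_preserves_sinusoid(self):
        # 1 s of a 50 Hz sinusoid at 800 Hz -> 3,200 samples, amplitude kept
        t = np.arange(800) / 800.0
        wave = np.sin(2 * np.pi * 50 * t)
        s = gyro_stream(np.vstack([wave, wave, wave]))
        out = resample_to_common_rate(s)
        assert out.actual_rate == 3200.0
        assert out.n_samples == 3200
        core = out.samples[0, 400:-400]
        assert abs(core.max() - 1.0) < 0.01
        assert abs(core.min() + 1.0) < 0.01

    def test_jittered_rate_length_arithmetic(self):
        # 3,180 Hz -> 3,200 Hz: length scales by 3200/3180 within one sample
        n_in = 3180
        s = accelerometer_stream(
            "left_acc", np.zeros((3, n_in)), actual_rate=3180.0
        )
        out = resample_to_common_rate(s)
        expected = n_in * 3200.0 / 3180.0
        assert abs(out.n_samples - expected) <= 1.0

    def test_band_limited_content_survives_jitter_correction(self):
        t = np.arange(3180) / 3180.0
        wave = np.sin(2 * np.pi * 50 * t)
        s = accelerometer_stream("left_acc", np.vstack([wave] * 3), actual_rate=3180.0)
        out = resample_to_common_rate(s)
        core = out.samples[0, 300:-300]
        assert abs(core.max() - 1.0) < 0.01

    def test_non_finite_samples_rejected(self):
        bad = np.zeros((3, 100))
        bad[0, 3] = np.inf
        s = accelerometer_stream("left_acc", bad, actual_rate=3100.0)
        with pytest.raises(ValueError, match="non-finite"):
            resample_to_common_rate(s)

    def test_norm_commutes_with_resampling_for_band_limited_signals(self):
        rng = np.random.default_rng(7)
        t = np.arange(1600) / 1600.0
        chans = np.vstack(
            [
                sum(
                    rng.uniform(0.5, 1) * np.sin(2 * np.pi * f * t + rng.uniform(0, 6))
                    for f in rng.uniform(10, 250, size=5)
                )
                for _ in range(3)
            ]
        )
        # an offset channel keeps the norm away from its |.|=0 kink, where
        # the square root would spread energy beyond the band
        chans[0] += 10.0
        s = accelerometer_stream("left_acc", chans, actual_rate=1600.0)
        out = resample_to_common_rate(s)
        norm_after = euclidean_norm(*out.samples)
        norm_before = euclidean_norm(*s.samples)
        norm_resampled = resample_to_common_rate(
            accelerometer_stream("left_acc", np.vstack([norm_before] * 3), actual_rate=1600.0)
        ).samples[0]
        core = slice(200, -200)
        scale = np.max(np.abs(norm_resampled[core]))
        assert np.allclose(
            norm_after[core], norm_resampled[core], atol=0.02 * scale
        )


class TestEuclideanNorm:
    def test_three_four_zero_gives_five(self):
        np.testing.assert_allclose(
            euclidean_norm(np.array([3.0]), np.array([4.0]), np.array([0.0])), [5.0]
        )

    def test_zeros_map_to_zeros(self):
        z = np.zeros(10)
        np.testing.assert_array_equal(euclidean_norm(z, z, z), z)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        x, y, z = rng.normal(size=(3, 50))
        expected = np.array(
            [np.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)]
        )
        np.testing.assert_allclose(euclidean_norm(x, y, z), expected, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            euclidean_norm(np.zeros(3), np.zeros(3), np.zeros(4))


class TestButterworthTriageFilter:
    def test_dc_gain_is_unity(self):
        out = butterworth_lowpass(np.full(2000, 7.5), 3200.0)
        np.testing.assert_allclose(out[-100:], 7.5, rtol=1e-6)

    def test_minus_3db_at_cutoff(self):
        # second-order Butterworth: |H(300 Hz)| = 1/sqrt(2)
        gain = _steady_state_gain(300.0)
        assert abs(gain - 1 / np.sqrt(2)) < 0.02 * 1 / np.sqrt(2)

    def test_analytic_magnitude_in_stopband(self):
        # analog second-order magnitude 1/sqrt(1+(f/fc)^4) approximates the
        # digital filter where f is well below Nyquist; near Nyquist the
        # bilinear design adds a zero, so attenuation is much stronger
        expected = 1 / np.sqrt(1 + (600 / 300) ** 4)
        gain = _steady_state_gain(600.0)
        assert abs(gain - expected) < 0.2 * expected
        assert _steady_state_gain(1500.0) < 0.005

    def test_magnitude_response_is_monotone_nonincreasing(self):
        from scipy.signal import butter, freqz

        b, a = butter(2, 300.0, btype="low", fs=3200.0)
        _, h = freqz(b, a, worN=np.arange(10.0, 1600.0, 10.0), fs=3200.0)
        mags = np.abs(h)
        assert np.all(np.diff(mags) <= 1e-12)

    def test_causality_no_response_before_input(self):
        x = np.zeros(400)
        x[200] = 1.0
        out = butterworth_lowpass(x, 3200.0)
        np.testing.assert_array_equal(out[:200], 0.0)

    def test_output_length_equals_input_length(self):
        assert butterworth_lowpass(np.ones(321), 3200.0).size == 321

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_lowpass(np.ones(100), 500.0, TriageConfig(cutoff_hz=300.0))


def _continuous_streams(norm_pulse_samples, n=3200, rate=3200.0):
    """Stream set whose left-acc norm has the given pulse indices at 20 g."""
    x = np.zeros((3, n))
    for idx, amp in norm_pulse_samples:
        x[0, idx] = amp
    streams = {
        "left_acc": accelerometer_stream("left_acc", x, actual_rate=rate),
        "centre_acc": accelerometer_stream("centre_acc", np.zeros((3, n))),
        "right_acc": accelerometer_stream("right_acc", np.zeros((3, n))),
        "gyro": gyro_stream(np.zeros((3, n // 4)), actual_rate=rate / 4),
    }
    return streams


class TestOnboardTrigger:
    def test_window_geometry_single_trigger(self):
        # trigger at sample 640 @ 3,200 Hz -> 64 samples lead-in, 256 tail
        caps = emulate_onboard_trigger(_continuous_streams([(640, 20.0)]))
        assert len(caps) == 1
        c = caps[0]
        assert c.trigger_index == 64  # 640 - 576
        assert c.streams["left_acc"].n_samples == 320  # samples [576, 896)
        assert c.streams["left_acc"].samples[0, 64] == 20.0
        assert c.streams["gyro"].n_samples == 80  # same span at 800 Hz

    def test_triggers_within_tail_merge(self):
        # 50 ms apart (160 samples) < 80 ms tail -> one merged capture
        caps = emulate_onboard_trigger(_continuous_streams([(640, 20.0), (800, 20.0)]))
        assert len(caps) == 1
        assert caps[0].streams["left_acc"].n_samples == 320 + 160

    def test_triggers_beyond_tail_split(self):
        caps = emulate_onboard_trigger(_continuous_streams([(640, 20.0), (1200, 20.0)]))
        assert len(caps) == 2

    def test_sub_threshold_peak_produces_no_capture(self):
        assert emulate_onboard_trigger(_continuous_streams([(640, 9.9)])) == []

    def test_window_clipped_at_stream_start(self):
        caps = emulate_onboard_trigger(_continuous_streams([(10, 20.0)]))
        assert len(caps) == 1
        assert caps[0].trigger_index == 10  # lead-in clipped to stream start

    def test_idempotent_on_own_output_window(self):
        (first,) = emulate_onboard_trigger(_continuous_streams([(640, 20.0)]))
        again = emulate_onboard_trigger(first.streams)
        assert len(again) == 1
        # re-triggering reproduces the window up to boundary clipping
        np.testing.assert_array_equal(
            again[0].streams["left_acc"].samples[0],
            first.streams["left_acc"].samples[0],
        )

    def test_missing_left_acc_rejected(self):
        streams = _continuous_streams([(640, 20.0)])
        del streams["left_acc"]
        with pytest.raises(ValueError, match="left_acc"):
            emulate_onboard_trigger(streams)


class TestTriage:
    def _capture_with_tone(self, freq, amp, n=1024):
        t = np.arange(n) / 3200.0
        x = np.zeros((3, n))
        x[0] = amp * np.sin(2 * np.pi * freq * t)
        c = make_capture(n_acc=n, n_gyro=n // 4)
        c.streams["left_acc"].samples = x
        return ik.process_capture(c)

    def test_low_frequency_impact_passes(self):
        # gain ~ 1 at 60 Hz; rectified 50 g tone stays far above 10 g
        assert self._capture_with_tone(60.0, 50.0).triage_passed

    def test_high_frequency_vocalization_rejected(self):
        # at 500 Hz the tone component is attenuated to ~0.34; the
        # rectified-norm DC (2/pi * 15 ~ 9.5 g) also stays below threshold
        assert not self._capture_with_tone(500.0, 14.0).triage_passed

    def test_all_zero_capture_rejected(self):
        assert not self._capture_with_tone(60.0, 0.0).triage_passed

    def test_corpus_level_triage_contract(self, processed_corpus):
        """Triage rejects every simulated yell and keeps strong low-frequency
        impacts (corpus-level assertion on the shared small corpus)."""
        _, processed, truths = processed_corpus
        yells = [p for p, t in zip(processed, truths) if t.event_class == "yelling"]
        impacts = [
            p
            for p, t in zip(processed, truths)
            if t.event_class == "impact"
            and t.peak_linear_acc >= 15
            and t.dominant_freq <= 150
        ]
        assert yells and impacts
        assert sum(p.triage_passed for p in yells) == 0
        assert all(p.triage_passed for p in impacts)

    def test_processed_capture_shape_and_rate(self, processed_corpus):
        _, processed, _ = processed_corpus
        p = processed[0]
        assert p.signals.shape[0] == len(SIGNAL_NAMES) == 12
        assert p.rate == 3200.0
        assert np.all(p.left_norm >= 0)
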