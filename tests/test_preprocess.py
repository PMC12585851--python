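import numpy as np
import pytest

from stridecost.io import SignalChannel
from stridecost.preprocess import (
    GaitEvents,
    SegmentationError,
    detect_heel_strikes,
    lowpass_filter,
    segment_strides,
    zero_swing_grf,
)
from stridecost.synthetic import SyntheticGaitConfig, generate_gait_trial


def sine_channel(freq, rate=100.0, duration=10.0, name="x_moment"):
    t = np.arange(int(duration * rate)) / rate
    return SignalChannel(name, np.sin(2 * np.pi * freq * t)), t


class TestLowpassFilter:
    def test_constant_signal_unchanged(self):
        ch = SignalChannel("c_moment", np.full(1000, 5.0))
        out = lowpass_filter(ch, cutoff=6.0, sampling_rate=100.0)
        np.testing.assert_allclose(out.samples[50:-50], 5.0, atol=1e-9)

    @pytest.mark.parametrize(
        "freq,min_gain,max_gain",
        [
            # analytic two-pass Butterworth magnitude: (1 + (f/fc)^(2n))^-1
            (1.0, 0.99, 1.001),  # passband: gain within 1% of unity
            (30.0, 0.0, 0.05),  # stopband: 30 Hz attenuated below 5%
        ],
    )
    def test_gain_against_analytic_magnitude_response(self, freq, min_gain, max_gain):
        ch, _ = sine_channel(freq)
        out = lowpass_filter(ch, cutoff=6.0, order=4, sampling_rate=100.0)
        amp = np.max(np.abs(out.samples[200:-200]))
        assert min_gain <= amp <= max_gain

    def test_cutoff_above_nyquist_rejected(self):
        ch, _ = sine_channel(1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(ch, cutoff=60.0, sampling_rate=100.0)

    def test_short_signal_rejected(self):
        ch = SignalChannel("s_moment", np.zeros(10))
        with pytest.raises(ValueError, match="too short"):
            lowpass_filter(ch, order=4, sampling_rate=100.0)


class TestHeelStrikeDetection:
    def test_constant_force_gives_no_events(self):
        ch = SignalChannel("grf_vertical", np.full(500, 500.0))
        events = detect_heel_strikes(ch, sampling_rate=100.0)
        assert len(events) == 0

    def test_square_wave_edges_found_within_one_sample(self):
        rate = 100.0
        period = np.r_[np.zeros(40), np.full(70, 700.0)]  # 0.4 s off, 0.7 s on
        y = np.tile(period, 6)
        ch = SignalChannel("grf_vertical", y)
        events = detect_heel_strikes(ch, threshold=30.0, sampling_rate=rate)
        expected = (np.arange(6) * 110 + 40) / rate
        assert len(events) == 6
        np.testing.assert_allclose(events.heel_strike_times, expected, atol=1.0 / rate)

    def test_non_grf_channel_rejected(self):
        ch = SignalChannel("knee_angle", np.zeros(100))
        with pytest.raises(TypeError, match="grf_force"):
            detect_heel_strikes(ch)

    def test_generator_ground_truth_recovered(self):
        # noise-free output: the construction guarantees one upward crossing
        # per stride, located within one sample of the continuous truth
        from conftest import NOISE_FREE

        cfg = SyntheticGaitConfig(seed=13, sigma_meas=dict(NOISE_FREE))
        trial, truth = generate_gait_trial(cfg)
        events = detect_heel_strikes(
            trial.channel("grf_vertical"), sampling_rate=trial.sampling_rate
        )
        assert len(events) == truth.heel_strike_times.size
        np.testing.assert_allclose(
            events.heel_strike_times,
            truth.heel_strike_times,
            atol=1.0 / trial.sampling_rate,
        )

    def test_event_count_preserved_under_measurement_noise(self, default_trial):
        trial, truth = default_trial
        events = detect_heel_strikes(
            trial.channel("grf_vertical"), sampling_rate=trial.sampling_rate
        )
        assert len(events) == truth.heel_strike_times.size

    def test_detection_robust_to_small_noise(self, quiet_trial):
        trial, _ = quiet_trial
        clean = trial.channel("grf_vertical")
        base = detect_heel_strikes(clean, sampling_rate=100.0)
        rng = np.random.default_rng(5)
        noisy = clean.replace_samples(clean.samples + rng.normal(0, 2.0, len(clean)))
        assert len(detect_heel_strikes(noisy, sampling_rate=100.0)) == len(base)


class TestZeroSwingGrf:
    def test_forced_example(self):
        chans = {"grf_vertical": SignalChannel("grf_vertical", [0.0, 10.0, 40.0, 10.0])}
        out = zero_swing_grf(chans, "grf_vertical", threshold=30.0)
        np.testing.assert_array_equal(out["grf_vertical"].samples, [0, 0, 40, 0])

    def test_stance_only_signal_unchanged(self):
        chans = {"grf_vertical": SignalChannel("grf_vertical", [100.0, 40.0, 35.0])}
        out = zero_swing_grf(chans, "grf_vertical")
        np.testing.assert_array_equal(out["grf_vertical"].samples, [100, 40, 35])

    def test_shear_zeroed_at_same_samples_as_vertical(self):
        rng = np.random.default_rng(3)
        vert = rng.uniform(0, 100, 200)
        shear = rng.normal(size=200)
        chans = {
            "grf_vertical": SignalChannel("grf_vertical", vert),
            "grf_fore_aft": SignalChannel("grf_fore_aft", shear),
        }
        out = zero_swing_grf(chans, "grf_vertical", threshold=30.0)
        swing = vert < 30.0
        assert np.all(out["grf_fore_aft"].samples[swing] == 0)
        np.testing.assert_array_equal(out["grf_fore_aft"].samples[~swing], shear[~swing])


class TestSegmentation:
    def events(self, n, spacing=1.1):
        return GaitEvents(np.arange(n) * spacing)

    def test_fixed_start_uses_consecutive_events(self, quiet_trial):
        trial, truth = quiet_trial
        events = GaitEvents(truth.stride_start_times)
        strides = segment_strides(trial, events, n_strides=5, start_index=0)
        assert len(strides) == 5
        starts = [s.t_start for s in strides]
        np.testing.assert_allclose(starts, truth.stride_start_times[:5], atol=0.01)

    def test_single_valid_start_ignores_seed(self, quiet_trial):
        trial, truth = quiet_trial
        events = GaitEvents(truth.stride_start_times[:6])
        a = segment_strides(trial, events, 5, "random", seed=1)
        b = segment_strides(trial, events, 5, "random", seed=999)
        assert [s.t_start for s in a] == [s.t_start for s in b]

    def test_too_few_events_reports_counts(self, quiet_trial):
        trial, truth = quiet_trial
        with pytest.raises(SegmentationError, match="6"):
            segment_strides(trial, GaitEvents(truth.stride_start_times[:3]), n_strides=5)

    def test_jittered_durations_match_ground_truth(self, default_trial):
        trial, truth = default_trial
        from stridecost.preprocess import detect_heel_strikes

        events = detect_heel_strikes(trial.channel("grf_vertical"), sampling_rate=100.0)
        strides = segment_strides(trial, events, n_strides=5, start_index=10)
        np.testing.assert_allclose(
            [s.duration for s in strides], truth.durations[10:15], atol=1.0 / 100.0
        )

    def test_stride_durations_tile_the_event_span(self, default_trial):
        trial, truth = default_trial
        events = GaitEvents(truth.heel_strike_times)
        strides = segment_strides(trial, events, n_strides=20, start_index=0)
        span = truth.heel_strike_times[20] - truth.heel_strike_times[0]
        total = sum(s.duration for s in strides)
        assert abs(total - span) <= 21.0 / trial.sampling_rate
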