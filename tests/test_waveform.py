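"""Tangent-angle beat metrics, screens and tallies."""
import numpy as np
import pytest

from axoasym import synthetic as syn
from axoasym import waveform as wf


def make_field(theta, fps=200.0):
    n, t = theta.shape
    return wf.TangentAngleField(
        theta=theta, s=np.linspace(0, 1, n), t=np.arange(t) / fps, fps=fps
    )


def travelling_field(f=28.0, a=0.5, w=1.5, fps=200.0, T=100, N=50, phase_sign=1.0):
    s = np.linspace(0, 1, N)
    t = np.arange(T) / fps
    theta = a * np.sin(2 * np.pi * f * t[None, :] + phase_sign * 2 * np.pi * w * s[:, None])
    return make_field(theta, fps)


class TestScreens:
    def test_constant_length_passes(self, noiseless_beat):
        _, series, _ = noiseless_beat
        assert wf.screen_by_length_cv(series)

    def test_alternating_lengths_fail(self):
        frames = np.zeros((4, 3, 2))
        for k, L in enumerate([20.0, 30.0, 20.0, 30.0]):
            frames[k, :, 0] = [0, L / 2, L]
        series = wf.WaveformSeries("c", 200.0, frames)
        cv = series.lengths.std() / series.lengths.mean()
        assert cv == pytest.approx(0.2)
        assert not wf.screen_by_length_cv(series, cv_max=0.05)

    def test_sinusoid_screen_passes_pure_tone(self):
        passed, r2 = wf.sinusoid_screen(travelling_field())
        assert passed and r2 > 0.999

    def test_sinusoid_screen_fails_white_noise(self, rng):
        theta = rng.normal(0, 0.3, (50, 100))
        passed, r2 = wf.sinusoid_screen(make_field(theta))
        assert not passed and r2 < 0.2

    def test_sinusoid_screen_r2_matches_signal_fraction(self, rng):
        # R^2 of tone + noise approaches (A^2/2) / (A^2/2 + sigma^2)
        a, sigma = 0.5, 0.1
        field = travelling_field(a=a)
        noisy = make_field(field.theta + rng.normal(0, sigma, field.theta.shape))
        _, r2 = wf.sinusoid_screen(noisy)
        expected = (a**2 / 2) / (a**2 / 2 + sigma**2)
        assert r2 == pytest.approx(expected, abs=0.05)


class TestSmoothing:
    def test_interpolating_limit_is_identity(self, noiseless_beat):
        _, series, _ = noiseless_beat
        out = wf.smooth_spacetime(series, smooth_s=0.0, smooth_t=0.0)
        assert np.allclose(out.frames, series.frames, atol=1e-9)

    def test_noise_reduction_on_pure_sinusoid(self, rng):
        spec = syn.SyntheticBeatSpec(frequency=10.0, noise_sd=0.0)
        series, _ = syn.generate_beat_series(spec)
        sd = 0.1
        noisy = wf.WaveformSeries(
            "c", series.fps, series.frames + rng.normal(0, sd, series.frames.shape)
        )
        # spatial pass absorbs ~2/3 of the noise sum of squares; the time
        # pass budget covers the remainder
        smoothed = wf.smooth_spacetime(
            noisy,
            smooth_s=0.7 * series.n_points * sd**2,
            smooth_t=0.2 * series.n_frames * sd**2,
        )
        resid_raw = np.abs(noisy.frames - series.frames).mean()
        resid_smooth = np.abs(smoothed.frames - series.frames).mean()
        assert resid_smooth < resid_raw / 2

    def test_static_straight_flagellum_stays_straight(self, rng):
        frames = np.zeros((100, 50, 2))
        frames[:, :, 0] = np.linspace(0, 20, 50)
        sd = 0.05
        noisy = wf.WaveformSeries("c", 200.0, frames + rng.normal(0, sd, frames.shape))
        # static signal: the full time budget flattens each point's series
        smoothed = wf.smooth_spacetime(
            noisy, smooth_s=50 * sd**2, smooth_t=100 * sd**2
        )
        # collinearity: residual to each frame's own best-fit line
        worst = 0.0
        for frame in smoothed.frames:
            coeffs = np.polyfit(frame[:, 0], frame[:, 1], 1)
            resid = frame[:, 1] - np.polyval(coeffs, frame[:, 0])
            worst = max(worst, np.abs(resid).max())
        assert worst < sd


class TestTangentAngles:
    def straight_series(self, angle=0.0, T=10, N=20):
        base = np.linspace(0, 15, N)
        frames = np.zeros((T, N, 2))
        frames[:, :, 0] = base * np.cos(angle)
        frames[:, :, 1] = base * np.sin(angle)
        return wf.WaveformSeries("c", 200.0, frames)

    def test_straight_on_axis_gives_zero(self):
        field = wf.compute_tangent_angles(self.straight_series())
        assert np.allclose(field.theta, 0.0, atol=1e-12)

    def test_rigid_rotation_against_fixed_axis(self):
        field = wf.compute_tangent_angles(
            self.straight_series(angle=0.3), body_axis=(1.0, 0.0)
        )
        assert np.allclose(field.theta, 0.3, atol=1e-12)

    def test_rigid_rotation_with_corotating_axis_is_invariant(self):
        field = wf.compute_tangent_angles(self.straight_series(angle=0.3))
        assert np.allclose(field.theta, 0.0, atol=1e-12)

    def test_coincident_points_rejected(self):
        frames = np.zeros((3, 4, 2))
        frames[:, :, 0] = [0.0, 1.0, 1.0, 2.0]
        with pytest.raises(ValueError, match="coincident"):
            wf.compute_tangent_angles(wf.WaveformSeries("c", 200.0, frames))

    def test_round_trip_matches_generating_wave(self):
        spec = syn.SyntheticBeatSpec(noise_sd=0.0)
        series, _ = syn.generate_beat_series(spec)
        field = wf.compute_tangent_angles(series)
        s = field.s
        t = field.t
        expected = spec.half_amplitude * np.sin(
            2 * np.pi * spec.frequency * t[None, :]
            + 2 * np.pi * spec.waves_per_flagellum * s[:, None]
        )
        # central-difference tangents average adjacent segment angles;
        # compare away from the one-sided ends
        assert np.abs(field.theta[1:-1] - expected[1:-1]).max() < 0.01


class TestAmplitude:
    def test_constant_field_zero(self):
        assert wf.angular_amplitude(make_field(np.full((10, 20), 0.7))) == 0.0

    def test_sampled_sinusoid_range(self):
        field = travelling_field(f=10.0, a=0.5)
        assert wf.angular_amplitude(field) == pytest.approx(1.0, rel=0.02)

    def test_offset_in_s_invariance(self, rng):
        field = travelling_field()
        offset = rng.normal(0, 1, (field.theta.shape[0], 1))
        shifted = make_field(field.theta + offset)
        assert wf.angular_amplitude(shifted) == pytest.approx(
            wf.angular_amplitude(field)
        )

    def test_cycle_amplitude_exact_at_coarse_sampling(self):
        # 40 Hz at 200 fps: 5 samples/cycle, raw range undershoots
        field = travelling_field(f=40.0, a=0.5)
        assert wf.beat_cycle_amplitude(field) == pytest.approx(1.0, rel=0.01)
        assert wf.angular_amplitude(field) < 0.96

    def test_amplitude_invariant_under_rigid_frame_rotation(self):
        spec = syn.SyntheticBeatSpec(noise_sd=0.0)
        series, _ = syn.generate_beat_series(spec)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = wf.WaveformSeries("c", series.fps, series.frames @ R.T)
        a0 = wf.angular_amplitude(wf.compute_tangent_angles(series))
        a1 = wf.angular_amplitude(wf.compute_tangent_angles(rotated))
        assert a1 == pytest.approx(a0, rel=1e-9)


def brute_force_dominant_frequency(theta, fps):
    """O(T^2) discrete-Fourier oracle: explicit sums, no FFT."""
    N, T = theta.shape
    detrended = theta - theta.mean(axis=1, keepdims=True)
    n_freq = T // 2 + 1
    power = np.zeros(n_freq)
    for k in range(n_freq):
        re = np.zeros(N)
        im = np.zeros(N)
        for t in range(T):
            re += detrended[:, t] * np.cos(2 * np.pi * k * t / T)
            im -= detrended[:, t] * np.sin(2 * np.pi * k * t / T)
        power[k] = np.mean(re**2 + im**2)
    k_best = 1 + int(np.argmax(power[1:]))
    return k_best * fps / T


class TestDominantFrequency:
    def test_on_bin_tone_exact(self):
        field = travelling_field(f=28.0, T=100, fps=200.0)
        assert wf.dominant_frequency(field) == 28.0

    def test_static_field_undefined(self):
        assert wf.dominant_frequency(make_field(np.full((10, 20), 0.4))) is None

    def test_two_tone_returns_stronger(self):
        s = np.linspace(0, 1, 30)[:, None]
        t = np.arange(100)[None, :] / 200.0
        theta = (np.sqrt(2.0) * np.sin(2 * np.pi * 20 * t - s)
                 + 1.0 * np.sin(2 * np.pi * 36 * t + 2 * s))
        assert wf.dominant_frequency(make_field(theta)) == 20.0

    def test_hann_window_agrees_on_bin(self):
        field = travelling_field(f=28.0)
        assert wf.dominant_frequency(field, window="hann") == 28.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            theta = rng.normal(0, 1, (8, 40))
            field = make_field(theta, fps=200.0)
            assert wf.dominant_frequency(field) == pytest.approx(
                brute_force_dominant_frequency(theta, 200.0)
            )
        field = travelling_field(f=28.0, T=60)
        assert wf.dominant_frequency(field) == pytest.approx(
            brute_force_dominant_frequency(field.theta, 200.0)
        )


class TestWaves:
    def test_standing_wave_has_zero_waves(self):
        s = np.linspace(0, 1, 50)[:, None]
        t = np.arange(100)[None, :] / 200.0
        theta = np.sin(2 * np.pi * 20 * t) * (1.0 + 0.5 * s)
        waves, _ = wf.waves_per_flagellum(make_field(theta))
        assert waves == pytest.approx(0.0, abs=1e-9)

    def test_travelling_wave_round_trip(self):
        waves, low_conf = wf.waves_per_flagellum(travelling_field(w=1.5))
        assert waves == pytest.approx(1.5, abs=0.01)
        assert not low_conf

    def test_noise_robustness_over_seeds(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            field = travelling_field(w=1.0)
            noisy = make_field(field.theta + rng.normal(0, 0.05, field.theta.shape))
            waves, _ = wf.waves_per_flagellum(noisy)
            errs.append(abs(waves - 1.0))
        assert max(errs) < 0.15


class TestSegments:
    def test_uniform_dynamics_symmetric(self):
        s = np.linspace(0, 1, 50)[:, None]
        t = np.arange(100)[None, :] / 200.0
        theta = 0.5 * np.sin(2 * np.pi * 20 * t) + 0 * s
        seg = wf.segment_metrics(make_field(theta))
        assert seg.proximal_amplitude == pytest.approx(seg.distal_amplitude)
        assert seg.proximal_frequency == seg.distal_frequency == 20.0

    def test_waves_split_between_halves(self):
        seg = wf.segment_metrics(travelling_field(w=1.5))
        assert seg.proximal_waves == pytest.approx(0.75, abs=0.1)
        assert seg.distal_waves == pytest.approx(0.75, abs=0.1)

    def test_amplitude_taper_distal_exceeds_proximal(self):
        s = np.linspace(0, 1, 50)[:, None]
        t = np.arange(100)[None, :] / 200.0
        theta = (0.5 * s) * np.sin(2 * np.pi * 20 * t - 2 * np.pi * s)
        seg = wf.segment_metrics(make_field(theta))
        assert seg.distal_amplitude > seg.proximal_amplitude

    def test_tiny_segment_rejected(self):
        field = travelling_field(N=4)
        with pytest.raises(ValueError, match="fewer than 3"):
            wf.segment_metrics(field)


class TestTally:
    def test_example_proportions(self):
        tally = wf.beat_type_tally(
            ["tip_to_base_continuous", "tip_to_base_continuous",
             "base_to_tip_asymmetric", "static_uncoordinated"]
        )
        assert tally.proportions["tip_to_base_continuous"] == 0.5
        assert tally.proportions["base_to_tip_asymmetric"] == 0.25
        assert tally.proportions["static_uncoordinated"] == 0.25
        assert tally.proportions["switch"] == 0.0
        assert sum(tally.proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wf.beat_type_tally([])

    def test_unknown_label_named(self):
        with pytest.raises(ValueError, match="wiggle"):
            wf.beat_type_tally(["switch", "wiggle"])

    def test_order_invariance_and_binomial_consistency(self, rng):
        p = np.array([0.5, 0.1, 0.2, 0.05, 0.15])
        labels = list(rng.choice(wf.BEAT_CLASSES, size=1000, p=p))
        tally = wf.beat_type_tally(labels)
        shuffled = wf.beat_type_tally(labels[::-1])
        assert tally.counts == shuffled.counts
        for cls, prob in zip(wf.BEAT_CLASSES, p):
            tol = 3 * np.sqrt(prob * (1 - prob) / 1000)
            assert abs(tally.proportions[cls] - prob) <= tol


class TestSignalSpeed:
    def test_beat_period(self):
        period, _ = wf.required_signal_speed(40.0, 25.0)
        assert period == pytest.approx(25.0)

    def test_required_speed(self):
        _, speed = wf.required_signal_speed(40.0, 25.0)
        assert speed == pytest.approx(1000.0)

    def test_unit_case(self):
        assert wf.required_signal_speed(1.0, 1.0) == (1000.0, 1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            wf.required_signal_speed(0.0, 25.0)


class TestPipeline:
    def test_full_pipeline_on_generator(self):
        spec = syn.SyntheticBeatSpec(frequency=28.0, half_amplitude=0.5,
                                     waves_per_flagellum=1.5, noise_sd=0.02,
                                     seed=4)
        series, truth = syn.generate_beat_series(spec)
        m = wf.analyze_series(series, with_segments=True)
        assert m.length_cv_passed and m.sinusoid_passed
        assert m.dominant_frequency == pytest.approx(truth["frequency"], abs=2.0)
        assert m.angular_amplitude == pytest.approx(
            truth["amplitude_range"], rel=0.05
        )
        assert m.waves_per_flagellum == pytest.approx(truth["waves"], abs=0.1)
        assert m.segments is not None

    def test_static_cell_reported_without_frequency(self):
        frames = np.zeros((10, 20, 2))
        frames[:, :, 0] = np.linspace(0, 15, 20)
        m = wf.analyze_series(wf.WaveformSeries("c", 200.0, frames))
        assert m.length_cv_passed
        assert m.dominant_frequency is None
        assert m.waves_per_flagellum is None
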