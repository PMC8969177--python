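import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meapipe import (
    DetectionParams,
    SpikeTrain,
    bandpass_filter,
    classify_active,
    default_template,
    detect_spikes,
    estimate_noise_sd,
    extract_waveforms,
    swtteo_energy,
    synthesize_trace,
    teager_energy,
    threshold_detect,
)

FS = 12_500.0


def sinusoid(freq, duration=1.0, fs=FS, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_stopband_rejection_at_100hz(self):
        x = sinusoid(100.0)
        y = bandpass_filter(x, FS)
        assert np.sqrt(np.mean(y**2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_passband_preserves_1khz(self):
        x = sinusoid(1000.0)
        y = bandpass_filter(x, FS)
        # forward-backward squares the ripple; allow a few percent
        assert np.sqrt(np.mean(y[2000:-2000] ** 2)) == pytest.approx(
            np.sqrt(np.mean(x[2000:-2000] ** 2)), rel=0.05
        )

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(bandpass_filter(np.zeros(5000), FS), 0.0)

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(5000), 5000.0)


class TestNoiseSd:
    def test_gaussian_consistency(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10e-6, int(60 * FS))
        assert estimate_noise_sd(x) == pytest.approx(10e-6, rel=0.02)

    def test_zero_trace(self):
        assert estimate_noise_sd(np.zeros(100)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sd(np.empty(0))

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, 10_000)
        assert estimate_noise_sd(scale * x) == pytest.approx(
            scale * estimate_noise_sd(x), rel=1e-9
        )

    def test_robust_to_sparse_spikes(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1.0, 100_000)
        x[::5000] += 50.0
        assert estimate_noise_sd(x) == pytest.approx(1.0, rel=0.05)


class TestThresholdDetect:
    def test_single_template_event_at_peak(self):
        template = default_template(FS)
        train = SpikeTrain(np.array([0.5]), 1.0)
        trace = synthesize_trace(train, template, 50e-6, 0.0, FS, seed=0)
        events = threshold_detect(trace, FS, sigma_v=10e-6)
        assert events.times_s.size == 1
        assert events.times_s[0] == pytest.approx(0.5, abs=1e-3)

    def test_subthreshold_pulses_ignored(self):
        trace = np.zeros(int(FS))
        trace[1000:12000:2500] = 3.0e-6  # 3.0 sigma with sigma forced to 1 uV
        events = threshold_detect(trace, FS, sigma_v=1e-6)
        assert events.times_s.size == 0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_threshold_sigma_ratio_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.normal(0, rng.uniform(1e-6, 1e-4), 5000)
        events = threshold_detect(trace, FS)
        assert events.threshold_v / events.sigma_v == pytest.approx(4.5, abs=1e-12)

    def test_dead_time_collapses_to_larger(self):
        trace = np.zeros(int(FS))
        trace[5000] = 10e-6
        trace[5005] = 20e-6  # 0.4 ms later, inside the 1 ms dead time
        events = threshold_detect(trace, FS, sigma_v=1e-6)
        assert events.times_s.size == 1
        assert abs(events.amplitudes_v[0]) == pytest.approx(20e-6)


class TestSwtteo:
    def test_teo_sinusoid_closed_form(self):
        a, f = 2.0, 700.0
        x = sinusoid(f, amplitude=a)
        psi = teager_energy(x)
        expected = a**2 * np.sin(2 * np.pi * f / FS) ** 2
        np.testing.assert_allclose(psi[1:-1], expected, rtol=1e-6)

    def test_zero_trace_zero_energy(self):
        np.testing.assert_array_equal(swtteo_energy(np.zeros(4096), FS), 0.0)

    def test_energy_nonnegative_and_same_length(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1e-5, 10_001)  # odd length exercises padding
        e = swtteo_energy(x, FS)
        assert e.shape == x.shape
        assert np.all(e >= 0)

    def test_peak_near_embedded_spike(self):
        template = default_template(FS)
        train = SpikeTrain(np.array([1.0]), 2.0)
        trace = synthesize_trace(train, template, 50e-6, 2e-6, FS, seed=1)
        e = swtteo_energy(bandpass_filter(trace, FS), FS)
        assert abs(np.argmax(e) / FS - 1.0) < 1e-3

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            swtteo_energy(np.zeros(2), FS)


class TestDetectSpikes:
    def test_empty_trace_empty_train(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 1e-6, int(FS)) * 0  # zero trace: no crossings
        train = detect_spikes(trace, FS)
        assert len(train) == 0
        assert train.duration_s == pytest.approx(1.0)

    def test_cancellation_never_adds_spikes(self):
        rng = np.random.default_rng(5)
        trace = rng.normal(0, 3e-6, int(10 * FS))
        filtered = bandpass_filter(trace, FS)
        n_threshold = threshold_detect(filtered, FS).times_s.size
        n_final = len(detect_spikes(trace, FS))
        assert n_final <= n_threshold

    def test_translation_equivariance(self):
        template = default_template(FS)
        train = SpikeTrain(np.array([0.5, 0.9]), 2.0)
        trace = synthesize_trace(train, template, 60e-6, 3e-6, FS, seed=6)
        shift = int(0.2 * FS)
        shifted = np.concatenate([trace[-shift:], trace[:-shift]])
        t0 = detect_spikes(trace, FS).times_s
        t1 = detect_spikes(shifted, FS).times_s
        inner0 = t0[(t0 > 0.1) & (t0 < 1.5)]
        matched = inner0 + shift / FS
        for t in matched:
            assert np.min(np.abs(t1 - t)) < 2e-4

    def test_high_snr_recall_precision(self):
        template = default_template(FS)
        rng = np.random.default_rng(8)
        times = np.sort(rng.uniform(0.5, 59.5, 100))
        times = times[np.concatenate(([True], np.diff(times) > 0.01))]
        truth = SpikeTrain(times, 60.0)
        trace = synthesize_trace(truth, template, 40e-6, 3e-6, FS, seed=8)
        detected = detect_spikes(trace, FS).times_s
        hits = sum(np.min(np.abs(detected - t)) <= 1e-3 for t in truth.times_s)
        recall = hits / len(truth)
        precision = sum(
            np.min(np.abs(truth.times_s - t)) <= 1e-3 for t in detected
        ) / max(len(detected), 1)
        assert recall >= 0.95 and precision >= 0.95


class TestClassifyActive:
    @pytest.mark.parametrize("n,expected", [(0, False), (10, False), (11, True)])
    def test_strict_ten_per_minute_rule(self, n, expected):
        train = SpikeTrain(np.linspace(1, 59, n), 60.0)
        assert classify_active(train) is expected


class TestExtractWaveforms:
    def test_cutout_length_and_edge_drop(self):
        trace = np.zeros(int(FS))
        train = SpikeTrain(np.array([0.0, 0.5]), 1.0)
        ws = extract_waveforms(trace, train, FS, window_pre_ms=1.0, window_post_ms=2.0)
        assert ws.cutouts.shape == (1, round(3e-3 * FS))
        assert ws.n_dropped_edge == 1

    def test_noiseless_cutout_recovers_template(self):
        template = default_template(FS)
        train = SpikeTrain(np.array([0.5]), 1.0)
        trace = synthesize_trace(train, template, 30e-6, 0.0, FS, seed=0)
        det = threshold_detect(trace, FS, sigma_v=1e-6)
        ws = extract_waveforms(
            trace, SpikeTrain(det.times_s, 1.0), FS, window_pre_ms=1.0, window_post_ms=1.0
        )
        scaled = template.waveform * 30e-6
        assert ws.cutouts.shape[0] == 1
        assert np.min(ws.cutouts[0]) == pytest.approx(scaled.min(), rel=1e-6)
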