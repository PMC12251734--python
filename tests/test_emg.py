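"""sEMG conditioning chain: filter responses, RMS envelope, segmentation."""

import numpy as np
import pytest

from cbeqc import emg

FS = 1000.0


def sine(freq, fs=FS, duration=2.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


def steady(x, fs=FS, trim_s=0.25):
    """Central steady-state region, excluding zero-phase filter transients."""
    k = int(trim_s * fs)
    return np.asarray(x)[k:-k]


class TestNotch:
    def test_kills_powerline(self):
        x = sine(50.0)
        assert rms(steady(emg.notch_filter(x, FS))) <= 0.1 * rms(steady(x))

    def test_passes_neighbouring_band(self):
        # within 1 dB at 50 +/- 20 Hz
        for f in (30.0, 70.0):
            x = sine(f)
            assert rms(emg.notch_filter(x, FS)) >= 10 ** (-1 / 20) * rms(x)

    def test_passes_100hz(self):
        x = sine(100.0)
        assert rms(emg.notch_filter(x, FS)) == pytest.approx(rms(x), rel=0.05)

    def test_zero_signal(self):
        np.testing.assert_allclose(emg.notch_filter(np.zeros(500), FS), 0.0)

    def test_rejects_super_nyquist_notch(self):
        with pytest.raises(ValueError):
            emg.notch_filter(np.zeros(500), fs=80.0, f0=50.0)


class TestBandpass:
    def test_removes_dc(self):
        x = 1.0 + sine(100.0)
        assert abs(np.mean(steady(emg.bandpass_filter(x, FS)))) < 1e-3

    @pytest.mark.parametrize("f", [5.0, 490.0])
    def test_stopband_attenuation(self, f):
        x = sine(f)
        assert rms(steady(emg.bandpass_filter(x, FS))) <= 0.1 * rms(steady(x))

    def test_passband_flat_at_100hz(self):
        x = sine(100.0)
        assert rms(emg.bandpass_filter(x, FS)) == pytest.approx(rms(x), rel=0.10)

    def test_linearity(self, rng):
        a = rng.standard_normal(2000)
        b = rng.standard_normal(2000)
        lhs = emg.bandpass_filter(a + b, FS)
        rhs = emg.bandpass_filter(a, FS) + emg.bandpass_filter(b, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_invalid_band_errors(self):
        with pytest.raises(ValueError):
            emg.bandpass_filter(np.zeros(100), FS, lo=450.0, hi=20.0)
        with pytest.raises(ValueError):
            emg.bandpass_filter(np.zeros(100), FS, lo=20.0, hi=600.0)


class TestWindowedRMS:
    def test_constant_signal(self):
        env = emg.windowed_rms(np.full(1000, 0.2), FS)
        assert env.n_windows == 19  # (1000 - 100) / 50 + 1
        np.testing.assert_allclose(env.values, 0.2)
        np.testing.assert_allclose(env.window_start_s, np.arange(19) * 0.05)

    def test_sine_window_rms(self):
        # 100 Hz amplitude 1: integer cycles per 100 ms window -> A / sqrt(2)
        env = emg.windowed_rms(sine(100.0, duration=1.0), FS)
        np.testing.assert_allclose(env.values, 1 / np.sqrt(2), atol=1e-6)

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(500)
        env = emg.windowed_rms(x, FS)
        w, h = 100, 50
        expected = [np.sqrt(np.mean(x[i * h:i * h + w] ** 2))
                    for i in range((len(x) - w) // h + 1)]
        np.testing.assert_allclose(env.values, expected, atol=1e-12)

    @pytest.mark.parametrize("n,w_ms,ov,count", [
        (1000, 100, 0.5, 19), (100, 100, 0.5, 1), (150, 100, 0.5, 2), (5000, 100, 0.5, 99),
    ])
    def test_window_count_formula(self, n, w_ms, ov, count):
        env = emg.windowed_rms(np.ones(n), FS, window_ms=w_ms, overlap=ov)
        assert env.n_windows == count

    def test_short_signal_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            emg.windowed_rms(np.ones(99), FS)


class TestNormalizeResample:
    def test_linear_ramp_is_fixed_point(self):
        env = emg.RMSEnvelope(FS, 100.0, 0.5, np.linspace(0.0, 1.0, 21),
                              np.arange(21) * 0.05)
        norm = emg.normalize_resample(env)
        assert len(norm.values) == 500
        np.testing.assert_allclose(norm.values, norm.time_norm, atol=1e-12)
        assert norm.values[0] == env.values[0] and norm.values[-1] == env.values[-1]

    def test_constant_envelope(self):
        env = emg.RMSEnvelope(FS, 100.0, 0.5, np.full(7, 0.3), np.arange(7) * 0.05)
        np.testing.assert_allclose(emg.normalize_resample(env).values, 0.3)

    def test_matches_piecewise_linear_oracle(self, rng):
        vals = rng.uniform(0, 1, size=13)
        env = emg.RMSEnvelope(FS, 100.0, 0.5, vals, np.arange(13) * 0.05)
        norm = emg.normalize_resample(env)
        t = np.linspace(0, 1, 13)
        tq = np.linspace(0, 1, 500)
        np.testing.assert_allclose(norm.values, np.interp(tq, t, vals), atol=1e-12)

    def test_too_few_windows(self):
        env = emg.RMSEnvelope(FS, 100.0, 0.5, np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            emg.normalize_resample(env)


class TestGaussianSmooth:
    def test_constant_preserved(self):
        np.testing.assert_allclose(emg.gaussian_smooth(np.full(100, 2.5)), 2.5)

    def test_impulse_peak_matches_kernel_height(self):
        x = np.zeros(501)
        x[250] = 1.0
        out = emg.gaussian_smooth(x, sigma=10.0)
        assert out[250] == pytest.approx(1 / (10 * np.sqrt(2 * np.pi)), rel=1e-3)

    def test_symmetry_preserved(self):
        x = np.abs(np.arange(-50, 51)).astype(float)
        out = emg.gaussian_smooth(x, sigma=3.0)
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ValueError):
            emg.gaussian_smooth(np.ones(10), sigma=0.0)


class TestSummaries:
    def test_mean_rms(self):
        env = emg.RMSEnvelope(FS, 100.0, 0.5, np.array([0.1, 0.3]), np.array([0.0, 0.05]))
        assert emg.mean_rms(env) == pytest.approx(0.2)

    def test_peak_rms_per_repetition(self):
        env = emg.RMSEnvelope(FS, 100.0, 0.5, np.array([0.0, 1.0, 0.0, 2.0, 0.0]),
                              np.arange(5) * 0.05)
        assert emg.peak_rms_per_repetition(env, [(0, 2), (2, 4)]) == [1.0, 2.0]
        assert emg.peak_rms_per_repetition(env, [(0, 5)]) == [2.0]
        with pytest.raises(ValueError):
            emg.peak_rms_per_repetition(env, [(3, 9)])

    def test_peak_rms_matches_bruteforce(self, rng):
        vals = rng.uniform(size=60)
        env = emg.RMSEnvelope(FS, 100.0, 0.5, vals, np.arange(60) * 0.05)
        segs = [(0, 20), (25, 40), (45, 60)]
        assert emg.peak_rms_per_repetition(env, segs) == [
            float(vals[s:e].max()) for s, e in segs]


class TestSegmentation:
    def _bursty_envelope(self, n_bursts=10, win_per_burst=12, gap=10):
        vals = []
        for _ in range(n_bursts):
            vals.extend(np.hanning(win_per_burst))
            vals.extend(np.zeros(gap))
        return emg.RMSEnvelope(FS, 100.0, 0.5, np.array(vals),
                               np.arange(len(vals)) * 0.05)

    def test_finds_ten_bursts(self):
        env = self._bursty_envelope()
        segs = emg.segment_repetitions(env, expected=10)
        assert len(segs) == 10
        assert all(s < e for s, e in segs)
        assert all(e0 <= s1 for (_, e0), (s1, _) in zip(segs, segs[1:]))

    def test_flat_envelope_reports_zero(self):
        env = emg.RMSEnvelope(FS, 100.0, 0.5, np.full(100, 0.2), np.arange(100) * 0.05)
        with pytest.raises(emg.SegmentationError) as exc:
            emg.segment_repetitions(env, expected=10)
        assert exc.value.detected == 0

    def test_markers_take_precedence(self):
        env = self._bursty_envelope()
        markers = [(0.0, 0.5), (1.0, 1.5)]
        segs = emg.segment_repetitions(env, expected=2, markers=markers)
        assert segs == [(0, 10), (20, 30)]


class TestChain:
    def test_envelope_nonnegative_and_order(self, rng):
        rec = emg.EMGRecording(fs=FS, signal=rng.standard_normal(3000) * 0.1)
        env = emg.process_recording(rec)
        assert np.all(env.values >= 0)
        # chain equals explicit notch -> bandpass -> rms composition
        manual = emg.windowed_rms(
            emg.bandpass_filter(emg.notch_filter(rec.signal, FS), FS), FS)
        np.testing.assert_allclose(env.values, manual.values, atol=1e-12)

    def test_csv_round_trip(self, tmp_path, rng):
        rec = emg.EMGRecording(fs=FS, signal=rng.standard_normal(500) * 0.05)
        path = tmp_path / "emg.csv"
        emg.write_emg_csv(rec, path)
        back = emg.read_emg_csv(path)
        assert back.fs == pytest.approx(FS)
        np.testing.assert_allclose(back.signal, rec.signal, atol=1e-12)
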