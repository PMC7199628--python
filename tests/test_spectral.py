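"""Spectral feature extraction: filtering, DFT, Welch PSD, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from eegmatch.signal_model import EEGSegment
from eegmatch.spectral import (SpectrumFeature, WelchConfig, band_power,
                               bandpass_filter, crop_band, dft,
                               extract_feature, mean_feature, rms_feature,
                               to_probability, welch_psd)

FS = 512.0


def sinusoid(freq, fs=FS, n=10_240, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def welch_oracle(x, fs, nperseg, noverlap, window):
    """Mean of individually computed one-sided windowed periodograms."""
    w = sps.get_window(window, nperseg)
    scale = fs * np.sum(w**2)
    step = nperseg - noverlap
    periodograms = []
    for start in range(0, len(x) - nperseg + 1, step):
        spec = np.abs(np.fft.rfft(x[start:start + nperseg] * w)) ** 2 / scale
        if nperseg % 2 == 0:
            spec[1:-1] *= 2.0  # all bins except DC and Nyquist
        else:
            spec[1:] *= 2.0
        periodograms.append(spec)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, np.mean(periodograms, axis=0)


class TestBandpass:
    def test_stopband_tone_attenuated(self):
        seg = EEGSegment("x", sinusoid(100.0), fs=FS)
        out = bandpass_filter(seg, 0.1, 70.0)
        assert rms_feature(out.samples) < 0.05 * rms_feature(seg.samples)

    def test_passband_tone_preserved(self):
        seg = EEGSegment("x", sinusoid(10.0), fs=FS)
        out = bandpass_filter(seg, 0.1, 70.0)
        assert rms_feature(out.samples) == pytest.approx(
            rms_feature(seg.samples), rel=0.05)
        assert out.n_samples == seg.n_samples

    def test_zero_signal_stays_zero(self):
        seg = EEGSegment("z", np.zeros(4096), fs=FS)
        out = bandpass_filter(seg, 0.1, 70.0)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        seg = EEGSegment("x", np.zeros(1024), fs=FS)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(seg, 0.1, 300.0)


class TestDft:
    def test_impulse_and_constant(self):
        np.testing.assert_allclose(dft([1, 0, 0, 0]), np.ones(4), atol=1e-12)
        np.testing.assert_allclose(dft([1, 1, 1, 1]), [4, 0, 0, 0], atol=1e-12)

    def test_matches_naive_quadratic_sum(self, rng):
        x = rng.standard_normal(16)
        n = len(x)
        naive = np.array([
            sum(x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n))
            for k in range(n)
        ])
        np.testing.assert_allclose(dft(x), naive, atol=1e-10)

    def test_inverse_recovers_signal(self, rng):
        x = rng.standard_normal(64)
        np.testing.assert_allclose(np.fft.ifft(dft(x)).real, x, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dft([])


class TestWelch:
    def test_sinusoid_peak_location(self):
        cfg = WelchConfig(fs=FS, nperseg=1024)
        spec = welch_psd(sinusoid(10.0), cfg)
        peak = spec.freqs[np.argmax(spec.values)]
        assert abs(peak - 10.0) <= 0.5

    def test_matches_mean_periodogram_oracle(self, rng):
        cfg = WelchConfig(fs=FS, nperseg=256, overlap_fraction=0.5)
        x = rng.standard_normal(2048)
        spec = welch_psd(x, cfg)
        freqs, expected = welch_oracle(x, FS, 256, cfg.noverlap, "hamming")
        np.testing.assert_array_equal(spec.freqs, freqs)
        np.testing.assert_allclose(spec.values, expected, rtol=1e-9, atol=1e-15)

    def test_white_noise_spectrum_flat(self):
        x = np.random.default_rng(5).standard_normal(40_960)
        spec = welch_psd(x, WelchConfig(fs=FS, nperseg=1024))
        spec = crop_band(spec, 1.0, 70.0)
        assert spec.values.max() / np.median(spec.values) < 5.0

    def test_zero_signal_gives_zero_spectrum(self):
        spec = welch_psd(np.zeros(4096), WelchConfig(fs=FS, nperseg=1024))
        assert np.all(spec.values == 0.0)

    def test_signal_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), WelchConfig(fs=FS, nperseg=1024))

    @pytest.mark.parametrize("nperseg", [512, 1024, 2048])
    def test_band_power_invariant_to_segment_length(self, nperseg):
        # total power of a unit sinusoid is amp^2/2 = 0.5 regardless of
        # the Welch subsegment length
        spec = welch_psd(sinusoid(10.0, n=20_480), WelchConfig(fs=FS, nperseg=nperseg))
        assert band_power(spec, 5.0, 15.0) == pytest.approx(0.5, rel=0.10)


class TestProbabilityNormalization:
    def test_simple_normalization(self):
        spec = SpectrumFeature([2.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        out = to_probability(spec, epsilon=0.0)
        np.testing.assert_allclose(out.values, [0.25, 0.25, 0.5])
        assert out.normalized

    def test_zero_bin_floored(self):
        out = to_probability(SpectrumFeature([0.0, 1.0], [0.0, 1.0]), epsilon=1e-12)
        assert out.values[0] == pytest.approx(1e-12, rel=1e-6)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_random_vector_sums_to_one(self, rng):
        spec = SpectrumFeature(rng.uniform(0, 5, 64), np.arange(64.0))
        out = to_probability(spec)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        spec = SpectrumFeature(rng.uniform(0.1, 5, 64), np.arange(64.0))
        once = to_probability(spec)
        twice = to_probability(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_zero_with_zero_epsilon_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            to_probability(SpectrumFeature([0.0, 0.0], [0.0, 1.0]), epsilon=0.0)


class TestCropBand:
    def test_crop_counts_bins_by_inequality(self):
        freqs = np.arange(0.0, 256.5, 0.5)
        spec = SpectrumFeature(np.ones_like(freqs), freqs)
        out = crop_band(spec, 0.1, 70.0)
        # bins 0.5 .. 70.0 inclusive
        assert out.freqs[0] == 0.5 and out.freqs[-1] == 70.0
        assert out.n_bins == 140

    def test_full_range_is_identity(self):
        spec = SpectrumFeature([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = crop_band(spec, 0.0, 10.0)
        np.testing.assert_array_equal(out.values, spec.values)

    def test_empty_band_rejected(self):
        spec = SpectrumFeature(np.ones(129), np.linspace(0, 256, 129))
        with pytest.raises(ValueError, match="does not intersect"):
            crop_band(spec, 300.0, 400.0)


class TestScalarFeatures:
    def test_closed_forms(self):
        assert mean_feature([1, 2, 3]) == 2.0
        assert rms_feature([3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_match_direct_summation(self, rng):
        x = rng.standard_normal(1000)
        assert mean_feature(x) == pytest.approx(sum(x) / len(x), abs=1e-12)
        assert rms_feature(x) == pytest.approx(
            (sum(v * v for v in x) / len(x)) ** 0.5, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_feature([])
        with pytest.raises(ValueError):
            rms_feature([])


class TestFeatureRegistry:
    def test_default_pipeline_returns_probability_spectrum(self, small_dataset, small_welch):
        seg = small_dataset.segments[0]
        spec = extract_feature(seg, welch=small_welch)
        assert spec.normalized
        assert spec.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert spec.freqs[0] >= 0.1 and spec.freqs[-1] <= 70.0

    def test_unknown_feature_rejected(self, small_dataset):
        with pytest.raises(KeyError, match="unknown feature"):
            extract_feature(small_dataset.segments[0], name="wavelet")

    def test_scalar_features_single_bin(self, small_dataset):
        spec = extract_feature(small_dataset.segments[0], name="rms")
        assert spec.n_bins == 1 and spec.values[0] > 0
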