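import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anaspec.audio_io import Waveform
from anaspec.spectral import (ANAConfig, SpectrogramImage, apply_ana,
                              complete_fft, feature_maps, peak_frequency,
                              positive_fft, render_spectrogram_image,
                              stft_spectrogram, texture_metrics,
                              wave_relations)


def _sine(freq, rate=1000, seconds=1.0):
    t = np.arange(int(rate * seconds)) / rate
    return Waveform(np.sin(2 * np.pi * freq * t), rate)


class TestWaveRelations:
    def test_frequency_determines_period(self):
        assert wave_relations(frequency=0.5).period == pytest.approx(2.0)

    def test_velocity_and_wavelength_determine_frequency(self):
        params = wave_relations(velocity=340.0, wavelength=1.7)
        assert params.frequency == pytest.approx(200.0)
        assert params.period == pytest.approx(1 / 200.0)

    def test_zero_period_rejected(self):
        with pytest.raises(ValueError):
            wave_relations(period=0.0)

    def test_inconsistent_redundant_pair_rejected(self):
        with pytest.raises(ValueError):
            wave_relations(frequency=2.0, period=1.0)

    def test_consistent_redundant_pair_accepted(self):
        assert wave_relations(frequency=2.0, period=0.5).frequency == 2.0


class TestFFT:
    def test_complete_fft_is_conjugate_symmetric_for_sine(self):
        spec = complete_fft(_sine(100))
        mags = spec.magnitudes
        peaks = spec.frequencies[np.argsort(mags)[-2:]]
        assert set(np.abs(peaks)) == {100.0}
        # real input: |X(-f)| == |X(f)|
        assert np.allclose(mags[1:], mags[1:][::-1], atol=1e-9)

    def test_constant_signal_is_pure_dc(self):
        spec = complete_fft(Waveform(np.full(64, 0.7), 8000))
        assert spec.magnitudes[0] == pytest.approx(0.7 * 64)
        assert np.all(spec.magnitudes[1:] < 1e-9)

    def test_parseval_energy_identity(self, random_waveform):
        spec = complete_fft(random_waveform)
        freq_energy = np.sum(spec.magnitudes ** 2) / spec.n
        time_energy = np.sum(random_waveform.samples ** 2)
        assert freq_energy == pytest.approx(time_energy, rel=1e-9)

    @pytest.mark.parametrize("n", [4, 63, 64, 1024, 4095])
    def test_parseval_over_sizes(self, n):
        rng = np.random.default_rng(n)
        wave = Waveform(rng.uniform(-1, 1, n), 8000)
        spec = complete_fft(wave)
        assert np.sum(spec.magnitudes ** 2) / n == pytest.approx(
            np.sum(wave.samples ** 2), rel=1e-9)

    def test_positive_fft_bin_count(self):
        spec = positive_fft(Waveform(np.zeros(1024), 8000))
        assert len(spec.magnitudes) == 513

    def test_one_sided_matches_two_sided_on_positive_bins(self, random_waveform):
        one = positive_fft(random_waveform)
        two = complete_fft(random_waveform)
        n = len(random_waveform)
        assert np.max(np.abs(one.magnitudes - two.magnitudes[: n // 2 + 1])) < 1e-9

    def test_linearity_of_magnitudes(self, random_waveform):
        base = positive_fft(random_waveform).magnitudes
        scaled = positive_fft(Waveform(3.5 * random_waveform.samples,
                                       8000)).magnitudes
        assert np.allclose(scaled, 3.5 * base, rtol=1e-9)

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            complete_fft(Waveform(np.array([]), 8000))


class TestPeakFrequency:
    def test_sine_peak(self):
        assert peak_frequency(positive_fft(_sine(100))) == pytest.approx(100.0)

    def test_tie_breaks_to_lower_frequency(self):
        t = np.arange(1000) / 1000.0
        two_tone = np.sin(2 * np.pi * 200 * t) + np.sin(2 * np.pi * 400 * t)
        assert peak_frequency(positive_fft(Waveform(two_tone, 1000))) == 200.0

    def test_dc_is_ignored(self):
        wave = Waveform(0.9 + 0.1 * _sine(100).samples, 1000)
        assert peak_frequency(positive_fft(wave)) == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            peak_frequency(positive_fft(Waveform(np.zeros(64), 8000)))

    def test_two_sided_rejected(self):
        with pytest.raises(ValueError):
            peak_frequency(complete_fft(_sine(100)))


class TestSTFT:
    def test_stationary_sine_peaks_in_every_frame(self):
        wave = _sine(100, rate=8000, seconds=1.0)
        spec = stft_spectrogram(wave, 256, 128)
        for row in spec.magnitudes:
            peak_bin = np.argmax(row[1:]) + 1
            assert spec.frequencies[peak_bin] == pytest.approx(100.0, abs=8000 / 256)

    def test_chirp_ridge_is_nondecreasing_vs_framewise_oracle(self):
        rate = 8000
        t = np.arange(rate) / rate
        chirp = np.sin(2 * np.pi * (200 * t + 0.5 * 400 * t ** 2))  # 200->600 Hz
        wave = Waveform(chirp, rate)
        spec = stft_spectrogram(wave, 512, 256)
        ridge = []
        for i in range(spec.magnitudes.shape[0]):
            # brute-force oracle: one-sided FFT of each windowed segment
            from scipy.signal.windows import hann
            seg = wave.samples[i * 256: i * 256 + 512] * hann(512, sym=False)
            oracle = np.abs(np.fft.rfft(seg))
            assert np.allclose(spec.magnitudes[i], oracle, atol=1e-6)
            ridge.append(np.argmax(oracle[1:]) + 1)
        assert all(b2 >= b1 for b1, b2 in zip(ridge, ridge[1:]))

    @pytest.mark.parametrize("n,window,hop", [
        (1000, 256, 128), (256, 256, 128), (1000, 256, 256), (999, 100, 7),
    ])
    def test_frame_count_formula(self, n, window, hop):
        wave = Waveform(np.random.default_rng(0).uniform(-1, 1, n), 8000)
        spec = stft_spectrogram(wave, window, hop)
        assert spec.magnitudes.shape[0] == 1 + (n - window) // hop

    def test_window_equal_to_signal_gives_one_frame(self):
        wave = Waveform(np.ones(256), 8000)
        assert stft_spectrogram(wave, 256, 128).magnitudes.shape[0] == 1

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="pad"):
            stft_spectrogram(Waveform(np.ones(100), 8000), 256, 128)

    def test_nonpositive_hop_rejected(self):
        with pytest.raises(ValueError):
            stft_spectrogram(Waveform(np.ones(300), 8000), 256, 0)


class TestANA:
    def test_doubles_magnitudes_exactly(self, random_waveform):
        spec = positive_fft(random_waveform)
        boosted = apply_ana(spec, ANAConfig(gain=2.0))
        assert np.array_equal(boosted.magnitudes, 2.0 * spec.magnitudes)
        assert np.array_equal(boosted.frequencies, spec.frequencies)

    def test_energy_quadruples_under_doubling(self, random_waveform):
        spec = positive_fft(random_waveform)
        boosted = apply_ana(spec)
        assert np.sum(boosted.magnitudes ** 2) == pytest.approx(
            4.0 * np.sum(spec.magnitudes ** 2), rel=1e-12)

    def test_bin_ratios_invariant(self, random_waveform):
        spec = positive_fft(random_waveform)
        boosted = apply_ana(spec)
        nz = spec.magnitudes > 1e-12
        assert np.allclose(boosted.magnitudes[nz] / spec.magnitudes[nz], 2.0)

    def test_zero_spectrum_fixed_point(self):
        spec = positive_fft(Waveform(np.zeros(64), 8000))
        assert np.all(apply_ana(spec).magnitudes == 0.0)

    def test_gain_below_one_rejected(self):
        with pytest.raises(ValueError):
            ANAConfig(gain=0.5)

    def test_spectrogram_ana_matches_time_domain_amplitude_doubling(self):
        # frequency-domain doubling == doubling the waveform first (linearity)
        wave = _sine(100, rate=8000)
        doubled = Waveform(2.0 * wave.samples * 0.5, 8000)  # keep in [-1,1]
        half = Waveform(0.5 * wave.samples, 8000)
        via_ana = apply_ana(stft_spectrogram(half, 256, 128))
        via_time = stft_spectrogram(doubled, 256, 128)
        assert np.allclose(via_ana.magnitudes, via_time.magnitudes, atol=1e-9)


class TestRendering:
    def _spec(self, seed=0):
        rng = np.random.default_rng(seed)
        return stft_spectrogram(Waveform(rng.uniform(-1, 1, 4000), 8000),
                                256, 128)

    def test_per_image_max_cell_hits_one(self):
        img = render_spectrogram_image(self._spec(), intensity_ref="per_image_max",
                                       colormap="gray", out_size=(32, 32))
        assert img.grayscale().max() == pytest.approx(1.0, abs=1e-6)

    def test_fixed_ceiling_rendering_is_pointwise_monotone_in_ana(self):
        spec = self._spec()
        ceiling = float(spec.magnitudes.max()) * 4.0
        before = render_spectrogram_image(spec, "gray", ceiling, (48, 48))
        after = render_spectrogram_image(apply_ana(spec), "gray", ceiling, (48, 48))
        assert np.all(after.grayscale() >= before.grayscale() - 1e-9)
        assert after.grayscale().sum() > before.grayscale().sum()

    def test_per_image_normalization_annihilates_ana(self):
        spec = self._spec()
        before = render_spectrogram_image(spec, "viridis", "per_image_max", (48, 48))
        after = render_spectrogram_image(apply_ana(spec), "viridis",
                                         "per_image_max", (48, 48))
        assert np.allclose(before.pixels, after.pixels, atol=1e-9)

    def test_frequency_axis_points_up(self):
        # pure high tone -> bright rows near the image top
        wave = _sine(3000, rate=8000, seconds=0.5)
        img = render_spectrogram_image(stft_spectrogram(wave, 256, 128),
                                       "gray", "per_image_max", (64, 64))
        gray = img.grayscale()
        assert gray[:32].sum() > gray[32:].sum()

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            render_spectrogram_image(self._spec(), out_size=(0, 32))


class TestTexture:
    def test_uniform_image_degenerate_metrics(self):
        img = SpectrogramImage(np.full((8, 8), 0.5))
        mean, var, hc, vc, energy, entropy = texture_metrics(img)
        assert (hc, vc) == (0.0, 0.0)
        assert energy == pytest.approx(1.0)
        assert entropy == pytest.approx(0.0)

    def test_checkerboard_horizontal_contrast(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        metrics = texture_metrics(SpectrogramImage(board.astype(float)))
        assert metrics[2] == pytest.approx(1.0)  # horizontal contrast
        assert metrics[3] == pytest.approx(1.0)

    def test_invariant_under_horizontal_flip(self):
        from anaspec.dataset import horizontal_flip
        rng = np.random.default_rng(3)
        img = SpectrogramImage(rng.uniform(size=(16, 16, 3)))
        assert np.allclose(texture_metrics(img),
                           texture_metrics(horizontal_flip(img)))

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            texture_metrics(SpectrogramImage(np.array([[0.5]])))


class TestFeatureMaps:
    def test_identity_kernel(self):
        rng = np.random.default_rng(0)
        img = SpectrogramImage(rng.uniform(size=(8, 8)))
        [out] = feature_maps(img, [np.array([[1.0]])])
        assert np.allclose(out, img.grayscale())

    def test_zero_kernel_dims(self):
        img = SpectrogramImage(np.random.default_rng(1).uniform(size=(10, 12)))
        [out] = feature_maps(img, [np.zeros((3, 3))])
        assert out.shape == (8, 10)
        assert np.all(out == 0.0)

    def test_matches_bruteforce_sliding_window(self):
        rng = np.random.default_rng(7)
        img = SpectrogramImage(rng.uniform(size=(16, 16)))
        kernel = np.full((3, 3), 1 / 9.0)
        [out] = feature_maps(img, [kernel])
        gray = img.grayscale()
        brute = np.empty((14, 14))
        for i in range(14):
            for j in range(14):
                brute[i, j] = gray[i:i + 3, j:j + 3].mean()
        assert np.max(np.abs(out - brute)) < 1e-9

    def test_oversized_kernel_rejected(self):
        img = SpectrogramImage(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            feature_maps(img, [np.ones((5, 5))])


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=2, max_value=512))
def test_one_sided_bin_count_property(n):
    wave = Waveform(np.linspace(-1, 1, n), 8000)
    assert len(positive_fft(wave).magnitudes) == n // 2 + 1
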