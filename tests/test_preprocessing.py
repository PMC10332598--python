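"""Signal-level pipeline: windows, STFT, frequency layouts, compression."""

import numpy as np
import pytest

from vocrep.config import SpectrogramConfig
from vocrep.presets import PRESETS, get_preset
from vocrep.preprocessing import (
    baseline_spectrogram_features,
    compress,
    compute_hop,
    compute_sample_duration,
    compute_spectrogram,
    denoise_median,
    extract_window,
    frequency_layout,
    mel_filterbank,
    resample,
    spectrogram,
    znorm,
)

# published hop values (ms) for each preset; the california thrasher row is
# the one-decimal rounding of the formula (82.13 samples = 1.86 ms -> 1.9)
HOP_TABLE = {
    "bengalese_finch": (23, 0.7),
    "california_thrasher": (82, 1.9),
    "cassin_vireo": (168, 3.8),
    "black_headed_grosbeak": (117, 2.6),
    "humpback_whale": (164, 14.9),
    "bottlenose_dolphin": (1496, 15.6),
}


class TestSampleDuration:
    @pytest.mark.parametrize(
        "durations, expected",
        [([1.0, 1.0, 1.0, 1.0], 1.0), ([1, 2, 3, 4], 3.25), ([2.0], 2.0)],
    )
    def test_third_quartile(self, durations, expected):
        assert compute_sample_duration(durations) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no annotated durations"):
            compute_sample_duration([])


class TestHop:
    @pytest.mark.parametrize("name", sorted(HOP_TABLE))
    def test_hop_matches_published_settings(self, name):
        cfg = get_preset(name)
        samples, ms = compute_hop(cfg.T, cfg.fs, cfg.nfft)
        assert (samples, ms) == HOP_TABLE[name]

    def test_window_longer_than_sample_raises(self):
        with pytest.raises(ValueError, match="not shorter"):
            compute_hop(0.001, 32_000, 256)


class TestExtractWindow:
    def test_zero_signal_gives_zero_window(self):
        w = extract_window(np.zeros(32_000), 0.5, 0.1, 32_000)
        assert w.shape == (3200,)
        assert not w.any()

    def test_file_start_is_left_padded(self):
        sig = np.ones(32_000)
        w = extract_window(sig, 0.0, 0.1, 32_000, normalise=False)
        assert not w[: 3200 // 2].any()
        assert (w[3200 // 2 :] == 1).all()

    def test_impulse_lands_at_window_centre(self):
        fs, T = 16_000, 0.1
        sig = np.zeros(16_000)
        center = 8000
        sig[center] = 1.0
        w = extract_window(sig, center / fs, T, fs, normalise=False)
        n = int(round(T * fs))
        assert w[n // 2] == 1.0
        assert w.sum() == 1.0

    def test_out_of_file_centre_raises_with_row_id(self):
        with pytest.raises(ValueError, match="row 42"):
            extract_window(np.zeros(100), 5.0, 0.01, 16_000, row_id=42)

    def test_window_is_znormalised(self, rng):
        w = extract_window(rng.normal(size=32_000), 0.5, 0.1, 32_000)
        assert abs(w.mean()) < 1e-10
        assert abs(w.std() - 1) < 1e-10


class TestResample:
    def test_identity_when_rates_match(self, rng):
        sig = rng.normal(size=1000)
        assert resample(sig, 32_000, 32_000) is sig

    def test_sine_peak_survives_downsampling(self):
        fs_in, fs_out, f0 = 32_000, 16_000, 100.0
        t = np.arange(fs_in) / fs_in
        out = resample(np.sin(2 * np.pi * f0 * t), fs_in, fs_out)
        assert len(out) == pytest.approx(fs_out, abs=1)
        peak_hz = np.abs(np.fft.rfft(out)).argmax() * fs_out / len(out)
        assert peak_hz == pytest.approx(f0, abs=fs_out / len(out))

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            resample(np.array([1.0, np.nan]), 32_000, 16_000)


class TestSpectrogram:
    def test_zero_window_gives_zero_magnitudes(self, small_config):
        mag = spectrogram(np.zeros(small_config.n_samples), small_config)
        assert mag.shape == (small_config.nfft // 2 + 1, 32)
        assert not mag.any()

    def test_bin_centre_sine_concentrates_in_one_row(self):
        cfg = get_preset("bengalese_finch")
        k = 32  # exact bin-centre frequency: k * fs / nfft
        t = np.arange(cfg.n_samples) / cfg.fs
        mag = spectrogram(np.sin(2 * np.pi * (k * cfg.fs / cfg.nfft) * t), cfg)
        # Hann mainlobe spans the bin and its two neighbours; elsewhere ~0
        row_energy = (mag**2).sum(axis=1)
        inside = row_energy[k - 1 : k + 2].sum()
        assert inside / row_energy.sum() > 0.999
        # constant over time
        assert np.allclose(mag[k], mag[k].mean(), rtol=1e-6)

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_128_columns_for_every_preset(self, name, rng):
        cfg = get_preset(name)
        mag = spectrogram(rng.normal(size=cfg.n_samples), cfg)
        assert mag.shape[1] == 128

    def test_window_shorter_than_nfft_raises(self, small_config):
        with pytest.raises(ValueError, match="shorter than nfft"):
            spectrogram(np.zeros(10), small_config)


class TestFrequencyLayout:
    @pytest.mark.parametrize("layout", ["mel", "linear"])
    def test_zero_in_zero_out(self, layout):
        cfg = SpectrogramConfig(fs=32_000, nfft=512, T=0.5, layout=layout)
        out = frequency_layout(np.zeros((257, 128)), cfg)
        assert out.shape == (128, 128)
        assert not out.any()

    def test_linear_pooling_covers_single_row(self):
        cfg = SpectrogramConfig(fs=32_000, nfft=1024, T=1.0, layout="linear")
        mag = np.zeros((513, 128))
        mag[100] = 1.0
        out = frequency_layout(mag, cfg)
        hot = np.flatnonzero(out.any(axis=1))
        # 513 rows -> 128 groups of ~4: row 100 falls in exactly one group
        assert len(hot) == 1
        edges = np.round(np.linspace(0, 513, 129)).astype(int)
        group = np.searchsorted(edges, 100, side="right") - 1
        assert hot[0] == group

    @pytest.mark.parametrize("nfft", [256, 512, 1024])
    def test_128_rows_independent_of_nfft(self, nfft, rng):
        cfg = SpectrogramConfig(fs=32_000, nfft=nfft, T=1.0, layout="mel")
        out = frequency_layout(rng.uniform(size=(nfft // 2 + 1, 128)), cfg)
        assert out.shape[0] == 128

    def test_linear_with_insufficient_resolution_raises(self, rng):
        cfg = SpectrogramConfig(fs=32_000, nfft=128, T=1.0, layout="linear")
        with pytest.raises(ValueError, match="insufficient frequency resolution"):
            frequency_layout(rng.uniform(size=(65, 128)), cfg)

    def test_mel_filterbank_spans_zero_to_nyquist(self):
        fb = mel_filterbank(32_000, 512, 128)
        assert fb.shape == (128, 257)
        assert (fb >= 0).all()
        # narrow low-frequency triangles may miss every FFT bin, but the
        # bulk of the bank must carry weight and reach Nyquist
        assert (fb.sum(axis=1) > 0).sum() > 100
        assert fb[-1, -1] >= 0 and fb[-1].sum() > 0


class TestCompress:
    def test_none_is_identity(self, rng):
        mag = rng.uniform(size=(16, 16))
        np.testing.assert_array_equal(compress(mag, "none"), mag)

    def test_log_of_constant_then_znorm_is_zero(self):
        out = znorm(compress(np.full((8, 8), 3.7), "log"))
        assert np.allclose(out, 0.0)

    def test_log_preserves_ordering(self, rng):
        mag = rng.uniform(size=200)
        out = compress(mag.reshape(1, -1), "log").ravel()
        i, j = rng.integers(0, 200, size=(2, 50))
        assert np.array_equal(np.sign(mag[i] - mag[j]), np.sign(out[i] - out[j]))

    def test_negative_magnitudes_raise(self):
        with pytest.raises(ValueError, match="non-negative"):
            compress(np.array([[-1.0]]), "log")

    def test_pcen_finite_and_shaped(self, rng):
        mag = rng.uniform(size=(32, 64))
        out = compress(mag, "pcen")
        assert out.shape == mag.shape
        assert np.isfinite(out).all()


class TestDenoiseMedian:
    def test_constant_maps_to_zero(self):
        assert not denoise_median(np.full((4, 9), 2.0)).any()

    def test_tone_row_removed_transient_kept(self):
        mag = np.zeros((3, 11))
        mag[1] = 1.0          # stationary tone row
        mag[2, 5] = 4.0       # transient (row median 0)
        out = denoise_median(mag)
        assert not out[1].any()
        assert out[2, 5] == 4.0

    def test_time_permutation_invariant_median(self, rng):
        mag = rng.uniform(size=(6, 21))
        perm = rng.permutation(21)
        np.testing.assert_allclose(
            np.sort(denoise_median(mag[:, perm]), axis=1),
            np.sort(denoise_median(mag), axis=1),
        )


class TestNormalisationAndBaseline:
    def test_znorm_moments(self, rng):
        out = znorm(rng.uniform(size=(128, 128)))
        assert abs(out.mean()) < 1e-5
        assert abs(out.std() - 1) < 1e-5

    def test_full_pipeline_output_is_normalised(self, rng):
        cfg = get_preset("bengalese_finch")
        spec = compute_spectrogram(rng.normal(size=cfg.n_samples), cfg)
        assert spec.shape == (128, 128)
        assert abs(spec.mean()) < 1e-5
        assert abs(spec.std() - 1) < 1e-5

    def test_zero_window_gives_zero_features(self):
        cfg = get_preset("bengalese_finch")
        assert not baseline_spectrogram_features(np.zeros(cfg.n_samples), cfg).any()

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_1024_features_for_every_preset(self, name, rng):
        cfg = get_preset(name)
        feats = baseline_spectrogram_features(rng.normal(size=cfg.n_samples), cfg)
        assert feats.shape == (1024,)

    def test_feature_determinism(self, rng):
        cfg = get_preset("bengalese_finch")
        w = rng.normal(size=cfg.n_samples)
        np.testing.assert_array_equal(
            baseline_spectrogram_features(w, cfg),
            baseline_spectrogram_features(w.copy(), cfg),
        )
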