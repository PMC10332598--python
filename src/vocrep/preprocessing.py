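"""From raw audio + annotations to fixed-size normalised spectrograms.

The pipeline cuts a fixed-duration window around the centre of each detected
vocalisation, z-normalises the waveform, computes an unpadded-Hann-window
magnitude STFT whose hop is chosen to produce exactly ``n_time`` time bins,
maps the frequency axis to ``n_mels`` bins (mel filterbank, or max-pooled
linear bins), optionally cancels stationary background noise, applies
dynamic-range compression (none / log / PCEN) and z-normalises each
spectrogram.  The result is a batch of ``(1, n_mels, n_time)`` arrays, the
auto-encoder's input space.

The 32x32 whole-spectrogram baseline (each spectro-temporal magnitude used
as an independent feature) is produced from the same 128x128 pipeline by
4x4 max-pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import read_wav
from .config import SpectrogramConfig

__all__ = [
    "SpectrogramBatch",
    "compute_sample_duration",
    "compute_hop",
    "extract_window",
    "resample",
    "spectrogram",
    "frequency_layout",
    "mel_filterbank",
    "compress",
    "pcen",
    "denoise_median",
    "znorm",
    "compute_spectrogram",
    "baseline_spectrogram_features",
    "build_batch",
]


# ---------------------------------------------------------------------------
# window-level settings


def compute_sample_duration(durations) -> float:
    """Fixed sample duration T: the 3rd quartile of all vocalisation durations.

    The 3rd quartile fully contains most vocalisations while not drowning the
    short ones in context.  Quartile convention: linear interpolation
    (``numpy.percentile`` default).
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("no annotated durations: cannot derive sample duration T")
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    return float(np.percentile(durations, 75))


def compute_hop(T: float, fs: float, nfft: int, n_time: int = 128) -> tuple[int, float]:
    """Hop size yielding ``n_time`` STFT bins: ``hop = (T*fs - nfft) / n_time``.

    Returns ``(hop_samples, hop_ms)``; the sample hop is rounded to the
    nearest integer, the millisecond value is the exact ratio rounded to one
    decimal for direct comparison with published settings tables.
    """
    span = T * fs - nfft
    if span <= 0:
        raise ValueError(
            f"FFT window ({nfft}) is not shorter than the sample (T*fs = {T * fs:.0f})"
        )
    hop_exact = span / n_time
    hop = int(round(hop_exact))
    hop_ms = round(hop_exact / fs * 1000.0, 1)
    return hop, hop_ms


def extract_window(
    signal: np.ndarray,
    center_time: float,
    T: float,
    fs: float,
    row_id: object = None,
    normalise: bool = True,
) -> np.ndarray:
    """Cut a ``round(T*fs)``-sample window centred on an annotation.

    Regions outside the file (and pre-cut files shorter than T) are
    zero-padded; the window is then z-normalised before frequency
    decomposition.  Indexing is 0-based with half-open windows: sample ``i``
    covers time ``[i/fs, (i+1)/fs)``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if not (0 <= center_time <= signal.size / fs):
        where = f" (row {row_id})" if row_id is not None else ""
        raise ValueError(
            f"annotation centre {center_time:.4f}s outside file of "
            f"{signal.size / fs:.4f}s{where}"
        )
    n = int(round(T * fs))
    center = int(round(center_time * fs))
    start = center - n // 2
    window = np.zeros(n, dtype=float)
    lo, hi = max(start, 0), min(start + n, signal.size)
    if hi > lo:
        window[lo - start : hi - start] = signal[lo:hi]
    return znorm(window) if normalise else window


def resample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling from ``fs_in`` to ``fs_out`` Hz.

    Identity when the rates already match; output length is
    ``len(signal) * fs_out / fs_in`` up to one sample.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise ValueError("signal contains non-finite samples")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return signal
    ratio = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(signal, ratio.numerator, ratio.denominator)


# ---------------------------------------------------------------------------
# STFT and frequency layout


def spectrogram(window: np.ndarray, config: SpectrogramConfig) -> np.ndarray:
    """Magnitude STFT with an unpadded (periodic) Hann window.

    Frames start at multiples of ``config.hop``; no frame zero-padding and no
    centring, so every frame covers real signal.  The hop formula yields one
    frame more than ``n_time``; trailing frames are dropped to give exactly
    ``n_time`` columns (onset alignment is preserved).  Returns an array of
    shape ``(nfft // 2 + 1, n_time)``.
    """
    window = np.asarray(window, dtype=float)
    nfft, hop, n_time = config.nfft, int(config.hop), config.n_time
    if window.size < nfft:
        raise ValueError(f"window ({window.size} samples) shorter than nfft ({nfft})")
    needed = nfft + hop * (n_time - 1)
    if window.size < needed:  # hop rounding can lose a frame; pad the tail
        window = np.pad(window, (0, needed - window.size))
    frames = np.lib.stride_tricks.sliding_window_view(window, nfft)[::hop][:n_time]
    taper = sps.get_window("hann", nfft, fftbins=True)
    return np.abs(np.fft.rfft(frames * taper, axis=1)).T


def _hz_to_mel(hz: np.ndarray) -> np.ndarray:
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    hz = np.asarray(hz, dtype=float)
    mel = hz / (200.0 / 3.0)
    log_region = hz >= 1000.0
    logstep = np.log(6.4) / 27.0
    mel = np.where(log_region, 15.0 + np.log(np.maximum(hz, 1e-12) / 1000.0) / logstep, mel)
    return mel


def _mel_to_hz(mel: np.ndarray) -> np.ndarray:
    mel = np.asarray(mel, dtype=float)
    hz = mel * (200.0 / 3.0)
    logstep = np.log(6.4) / 27.0
    return np.where(mel >= 15.0, 1000.0 * np.exp(logstep * (mel - 15.0)), hz)


def mel_filterbank(fs: float, nfft: int, n_mels: int = 128) -> np.ndarray:
    """Triangular mel filters from 0 Hz to Nyquist, Slaney-normalised.

    Returns a ``(n_mels, nfft // 2 + 1)`` projection matrix; each filter is
    scaled to unit area over its band so filter outputs are comparable
    across the frequency axis.
    """
    fft_freqs = np.linspace(0, fs / 2, nfft // 2 + 1)
    mel_edges = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2), n_mels + 2)
    hz_edges = _mel_to_hz(mel_edges)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lower, center, upper = hz_edges[i : i + 3]
        up = (fft_freqs - lower) / max(center - lower, 1e-12)
        down = (upper - fft_freqs) / max(upper - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (upper - lower)  # Slaney area normalisation
    return fb


def _pool_edges(n_in: int, n_out: int) -> np.ndarray:
    """Boundaries splitting ``n_in`` rows into ``n_out`` contiguous groups."""
    return np.round(np.linspace(0, n_in, n_out + 1)).astype(int)


def frequency_layout(mag: np.ndarray, config: SpectrogramConfig) -> np.ndarray:
    """Reduce the frequency axis to ``n_mels`` bins.

    ``layout="mel"`` projects through a 128-filter mel filterbank spanning 0
    to Nyquist; ``layout="linear"`` max-pools contiguous groups of linear
    frequency bins so the bin count is independent of the FFT size.
    """
    mag = np.asarray(mag, dtype=float)
    n_freq = config.nfft // 2 + 1
    if mag.shape[0] != n_freq:
        raise ValueError(f"expected {n_freq} frequency rows, got {mag.shape[0]}")
    if config.layout == "mel":
        return mel_filterbank(config.fs, config.nfft, config.n_mels) @ mag
    if n_freq < config.n_mels:
        raise ValueError(
            f"cannot max-pool {n_freq} linear bins down to {config.n_mels}: "
            "insufficient frequency resolution (increase nfft)"
        )
    edges = _pool_edges(n_freq, config.n_mels)
    return np.stack([mag[a:b].max(axis=0) for a, b in zip(edges[:-1], edges[1:])])


# ---------------------------------------------------------------------------
# dynamic-range compression and normalisation


def pcen(
    mag: np.ndarray,
    smoothing: float = 0.025,
    gain: float = 0.98,
    bias: float = 2.0,
    power: float = 0.5,
    eps: float = 1e-6,
) -> np.ndarray:
    """Per-channel energy normalisation.

    A first-order IIR filter smooths each frequency channel over time
    (coefficient ``smoothing``); magnitudes are divided by the smoothed
    energy raised to ``gain``, then root-compressed:
    ``((E / (eps + M)**gain) + bias)**power - bias**power``.
    """
    E = np.asarray(mag, dtype=float)
    b, a = [smoothing], [1.0, smoothing - 1.0]
    zi = (1.0 - smoothing) * E[..., :1]  # start the smoother at M[0] = E[0]
    M, _ = sps.lfilter(b, a, E, axis=-1, zi=zi)
    return (E / (eps + M) ** gain + bias) ** power - bias**power


#: Floor added before the log, relative to the max-normalised magnitude.
LOG_EPS = 1e-8


def compress(mag: np.ndarray, mode: str) -> np.ndarray:
    """Dynamic-range compression of non-negative magnitudes.

    ``none`` is the identity; ``log`` rescales by the spectrogram maximum and
    applies ``log(x + 1e-8)``; ``pcen`` applies per-channel energy
    normalisation with the defaults of :func:`pcen`.  (Per-spectrogram
    z-normalisation happens afterwards, in the batch pipeline.)
    """
    mag = np.asarray(mag, dtype=float)
    if (mag < 0).any():
        raise ValueError("magnitudes must be non-negative")
    if mode == "none":
        return mag
    if mode == "log":
        peak = mag.max()
        scaled = mag / peak if peak > 0 else mag
        return np.log(scaled + LOG_EPS)
    if mode == "pcen":
        return pcen(mag)
    raise ValueError(f"unknown compression mode {mode!r}")


def denoise_median(mag: np.ndarray) -> np.ndarray:
    """Stationary-noise cancellation: subtract each frequency row's median.

    Relatively stationary background (a constant tone row, broadband hum)
    has a high per-row median over time and is removed; transient content
    survives.  Negative residuals are clipped at zero so the output remains
    a valid magnitude array.
    """
    mag = np.asarray(mag, dtype=float)
    if mag.ndim != 2:
        raise ValueError("expected a 2-D spectrogram")
    return np.maximum(mag - np.median(mag, axis=1, keepdims=True), 0.0)


def znorm(x: np.ndarray, axis=None) -> np.ndarray:
    """Z-normalise to zero mean, unit standard deviation.

    Constant input (zero variance) maps to all zeros.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=axis is not None)
    sd = x.std(axis=axis, keepdims=axis is not None)
    sd = np.where(sd > 0, sd, 1.0) if np.ndim(sd) else (sd if sd > 0 else 1.0)
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# full pipeline


def compute_spectrogram(window: np.ndarray, config: SpectrogramConfig) -> np.ndarray:
    """Window → normalised ``(n_mels, n_time)`` spectrogram (full pipeline)."""
    mag = spectrogram(window, config)
    mag = frequency_layout(mag, config)
    if config.denoise:
        mag = denoise_median(mag)
    out = compress(mag, config.compression)
    if config.znorm_scope == "per_spectrogram":
        out = znorm(out)
    return out


def _max_pool2d(x: np.ndarray, factor: int) -> np.ndarray:
    h, w = x.shape
    return x.reshape(h // factor, factor, w // factor, factor).max(axis=(1, 3))


def baseline_spectrogram_features(window: np.ndarray, config: SpectrogramConfig) -> np.ndarray:
    """Whole-spectrogram baseline: 32x32 magnitudes flattened to 1024 features.

    Sample duration, sampling rate and FFT window match the auto-encoder
    path; the 32x32 image is the 4x4 max-pool of the standard 128x128
    spectrogram, so both representations share one code path.
    """
    spec = compute_spectrogram(window, config)
    factor = config.n_mels // 32
    if config.n_mels % 32 or config.n_time % 32:
        raise ValueError("baseline features require spectrogram dims divisible by 32")
    return _max_pool2d(spec, factor).ravel()


@dataclass
class SpectrogramBatch:
    """A stack of normalised spectrograms aligned with annotation rows.

    ``values`` has shape ``(batch, 1, n_mels, n_time)``; ``ids`` holds one
    identifier per spectrogram, aligned with the annotation table rows the
    batch was built from.
    """

    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.ids = np.asarray(self.ids)
        if self.values.ndim != 4 or self.values.shape[1] != 1:
            raise ValueError(f"expected shape (batch, 1, F, T), got {self.values.shape}")
        if len(self.ids) != len(self.values):
            raise ValueError("ids and values are misaligned")

    def __len__(self) -> int:
        return len(self.values)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, values=self.values, ids=self.ids)

    @classmethod
    def load(cls, path: str | Path) -> "SpectrogramBatch":
        with np.load(path, allow_pickle=False) as archive:
            return cls(values=archive["values"], ids=archive["ids"])


def build_batch(
    table: pd.DataFrame,
    config: SpectrogramConfig,
    audio_root: str | Path = ".",
) -> SpectrogramBatch:
    """Compute spectrograms for every annotation row.

    Audio files are read once each and cached; files whose sampling rate
    differs from ``config.fs`` are resampled.  Row ids are
    ``"<filename>#<row-index>"``.
    """
    audio_root = Path(audio_root)
    cache: dict[str, tuple[np.ndarray, float]] = {}
    specs, ids = [], []
    for idx, row in table.iterrows():
        fname = row["filename"]
        if fname not in cache:
            sig, fs_in = read_wav(audio_root / fname)
            if fs_in != config.fs:
                sig = resample(sig, fs_in, config.fs)
            cache[fname] = (sig, config.fs)
        sig, _ = cache[fname]
        window = extract_window(sig, row["center_s"], config.T, config.fs, row_id=idx)
        specs.append(compute_spectrogram(window, config))
        ids.append(f"{fname}#{idx}")
    values = np.stack(specs)[:, None, :, :]
    return SpectrogramBatch(values=values, ids=np.array(ids))
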