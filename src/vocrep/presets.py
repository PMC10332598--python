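"""Named spectrogram presets for the benchmark repertoires.

Each preset pins the three dataset-specific signal settings — sampling rate
``fs``, FFT window ``nfft`` and sample duration ``T`` — for one of the
published bird / cetacean repertoires the method was benchmarked on.  The
hop size is derived, not stored: ``hop = (T*fs - nfft) / 128`` samples.
"""

from __future__ import annotations

from .config import SpectrogramConfig

__all__ = ["PRESETS", "get_preset"]

# fs (Hz), nfft (samples), T (s)
_PRESET_SETTINGS: dict[str, tuple[float, int, float]] = {
    "bengalese_finch": (32_000, 256, 0.1),
    "california_thrasher": (44_100, 512, 0.25),
    "cassin_vireo": (44_100, 512, 0.5),
    "black_headed_grosbeak": (44_100, 512, 0.35),
    "humpback_whale": (11_025, 1024, 2.0),
    "bottlenose_dolphin": (96_000, 512, 2.0),
}

PRESETS: dict[str, SpectrogramConfig] = {
    name: SpectrogramConfig(fs=fs, nfft=nfft, T=T)
    for name, (fs, nfft, T) in _PRESET_SETTINGS.items()
}


def get_preset(name: str) -> SpectrogramConfig:
    """Return a fresh :class:`SpectrogramConfig` for a named repertoire."""
    try:
        fs, nfft, T = _PRESET_SETTINGS[name]
    except KeyError:
        known = ", ".join(sorted(_PRESET_SETTINGS))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None
    return SpectrogramConfig(fs=fs, nfft=nfft, T=T)
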