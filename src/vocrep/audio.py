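"""PCM WAV reading and writing as float arrays."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav"]

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as a mono float64 signal in [-1, 1].

    Integer PCM is scaled by its type's full range; multi-channel audio is
    averaged down to mono.  Returns ``(signal, sampling_rate)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    fs, data = wavfile.read(path)
    signal = np.asarray(data)
    if signal.dtype in _INT_SCALE:
        offset = 2**7 if signal.dtype == np.dtype("uint8") else 0
        signal = (signal.astype(np.float64) - offset) / _INT_SCALE[np.dtype(data.dtype)]
    else:
        signal = signal.astype(np.float64)
    if signal.ndim > 1:
        signal = signal.mean(axis=1)
    return signal, float(fs)


def write_wav(path: str | Path, signal: np.ndarray, fs: float) -> None:
    """Write a float signal as 32-bit float PCM WAV."""
    wavfile.write(Path(path), int(round(fs)), np.asarray(signal, dtype=np.float32))
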