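"""Run configuration objects and their YAML round-trip.

Three dataclasses hold every tunable of the pipeline:

* :class:`SpectrogramConfig` — signal-level settings (sampling rate, FFT
  window, sample duration, frequency layout, dynamic-range compression).
* :class:`AutoEncoderSpec` — architecture of the convolutional auto-encoder.
* :class:`TrainConfig` — optimiser, batching, loss choice and stopping rule.

All three serialise to a flat ``key: value`` YAML dialect so a whole run can
be reproduced from one config file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SpectrogramConfig",
    "AutoEncoderSpec",
    "TrainConfig",
    "load_config",
    "save_config",
]


@dataclass
class SpectrogramConfig:
    """Settings that turn an audio window into a fixed-size spectrogram.

    The output spectrogram has shape ``(n_mels, n_time)`` which must factor
    as ``(k_f * 2**n_halvings, k_t * 2**n_halvings)`` so that the
    auto-encoder's stride-2 halvings and factor-2 up-samplings invert each
    other exactly.  Defaults give the standard 128 x 128 layout
    (``k_f = k_t = 4``, ``n_halvings = 5``).

    Parameters
    ----------
    fs : sampling rate in Hz.
    nfft : FFT window length in samples (unpadded Hann window).
    T : sample duration in seconds; one fixed-length window is cut around
        the centre of every annotated vocalisation.
    hop : STFT hop in samples.  Derived from ``(T*fs - nfft) / n_time``
        when not given explicitly.
    layout : ``"mel"`` (128-filter mel filterbank up to Nyquist) or
        ``"linear"`` (max-pooled linear-frequency bins).
    compression : ``"none"``, ``"log"`` or ``"pcen"``.
    denoise : subtract each frequency row's median over time before
        compression (stationary background-noise cancellation).
    znorm_scope : ``"per_spectrogram"`` (default) or ``"per_dataset"``.
    """

    fs: float
    nfft: int
    T: float
    hop: int | None = None
    n_mels: int = 128
    n_time: int = 128
    layout: str = "mel"
    compression: str = "log"
    denoise: bool = False
    znorm_scope: str = "per_spectrogram"
    k_f: int = 4
    k_t: int = 4
    n_halvings: int = 5

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.nfft >= self.T * self.fs:
            raise ValueError(
                f"FFT window ({self.nfft} samples) must be shorter than the "
                f"sample window (T*fs = {self.T * self.fs:.0f} samples)"
            )
        if self.n_mels != self.k_f * 2**self.n_halvings:
            raise ValueError(
                f"n_mels={self.n_mels} must equal k_f*2^n = "
                f"{self.k_f * 2 ** self.n_halvings}"
            )
        if self.n_time != self.k_t * 2**self.n_halvings:
            raise ValueError(
                f"n_time={self.n_time} must equal k_t*2^n = "
                f"{self.k_t * 2 ** self.n_halvings}"
            )
        if self.layout not in ("mel", "linear"):
            raise ValueError(f"unknown frequency layout {self.layout!r}")
        if self.compression not in ("none", "log", "pcen"):
            raise ValueError(f"unknown compression {self.compression!r}")
        if self.znorm_scope not in ("per_spectrogram", "per_dataset"):
            raise ValueError(f"unknown znorm scope {self.znorm_scope!r}")
        if self.hop is None:
            self.hop = int(round((self.T * self.fs - self.nfft) / self.n_time))
        if self.hop <= 0:
            raise ValueError(f"hop must be positive, got {self.hop}")

    @property
    def n_samples(self) -> int:
        """Window length in samples, ``round(T * fs)``."""
        return int(round(self.T * self.fs))


@dataclass
class AutoEncoderSpec:
    """Architecture of the convolutional auto-encoder.

    The encoder stacks ``n_blocks`` stride-2 3x3 convolutions; channel width
    starts at ``base_channels`` and doubles at each block until the last,
    whose width is fixed by the bottleneck: after ``n_blocks`` halvings a
    ``(h, w)`` input leaves ``(h/2^n) * (w/2^n)`` spatial positions, so the
    last block carries ``bottleneck_dim / (h/2^n * w/2^n)`` channels and a
    plain flatten produces the bottleneck vector.  The decoder mirrors this
    with factor-2 nearest-neighbour up-sampling followed by two convolution
    blocks per stage.
    """

    n_blocks: int = 5
    kernel: int = 3
    base_channels: int = 32
    bottleneck_dim: int = 256
    input_shape: tuple[int, int, int] = (1, 128, 128)

    def __post_init__(self) -> None:
        self.input_shape = tuple(self.input_shape)  # type: ignore[assignment]
        _, h, w = self.input_shape
        f = 2**self.n_blocks
        if h % f or w % f:
            raise ValueError(
                f"input spatial dims {(h, w)} must be divisible by 2^{self.n_blocks}"
            )
        if self.bottleneck_dim % self.bottleneck_spatial != 0:
            raise ValueError(
                f"bottleneck_dim={self.bottleneck_dim} must be divisible by the "
                f"final spatial size {self.bottleneck_spatial}"
            )

    @property
    def bottleneck_spatial(self) -> int:
        _, h, w = self.input_shape
        f = 2**self.n_blocks
        return (h // f) * (w // f)

    @property
    def encoder_channels(self) -> list[int]:
        """Channel widths of the encoder blocks, e.g. [32, 64, 128, 256, 16]."""
        widths = [self.base_channels * 2**i for i in range(self.n_blocks - 1)]
        widths.append(self.bottleneck_dim // self.bottleneck_spatial)
        return widths


@dataclass
class TrainConfig:
    """Optimisation settings for auto-encoder training.

    ``window`` is the length (in steps) of the two loss windows compared by
    the stopping rule: stop once the median loss of the last ``window`` steps
    no longer decreases relative to the previous ``window`` steps.
    ``max_steps`` guarantees termination even if that rule never fires.
    """

    batch_size: int = 128
    learning_rate: float = 1e-3
    window: int = 1000
    loss: str = "perceptual"
    seed: int = 0
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.loss not in ("perceptual", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")


_SECTIONS = {
    "spectrogram": SpectrogramConfig,
    "autoencoder": AutoEncoderSpec,
    "training": TrainConfig,
}


def save_config(path: str | Path, **sections: Any) -> None:
    """Write config dataclasses to a YAML file, one top-level key per section."""
    doc = {}
    for name, obj in sections.items():
        doc[name] = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config; known sections are rebuilt into their dataclasses."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {}
    for name, value in doc.items():
        cls = _SECTIONS.get(name)
        out[name] = cls(**value) if cls is not None and isinstance(value, dict) else value
    return out
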