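"""Convolutional auto-encoder for vocalisation spectrograms.

The encoder is a stack of five stride-2 3x3 convolution blocks (channel
width doubling from 32 until the last block, each convolution followed by
batch normalisation and ReLU except the final, linear one); flattening the
last block's ``4 x 4 x (D/16)`` output yields the ``D``-dimensional
bottleneck embedding.  The decoder mirrors it: five stages of factor-2
nearest-neighbour up-sampling followed by two convolution blocks each, and
a final linear 1-channel convolution (inputs are z-normalised, hence
signed, so no output squashing).

Training minimises either plain MSE between input and reconstruction or a
*perceptual* loss: the MSE between feature maps of a frozen third-party
convolutional feature extractor, which emphasises salient foreground
structure (frequency contours) over background noise.  The extractor is
pluggable; the shipped default is a seeded random-weight multi-scale
convolutional filterbank (see :class:`RandomConvExtractor`), and any object
with the same ``layers`` / ``taps`` contract — e.g. a pretrained image
network — can be substituted.

Training runs Adam until the median loss over the last ``window`` steps
stops decreasing relative to the previous ``window`` steps (or a hard step
cap is reached).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import AutoEncoderSpec, TrainConfig
from .nn import DTYPE, Adam, BatchNorm2d, Conv2d, Layer, ReLU, Sequential, UpsampleNearest2x

__all__ = [
    "ConvAutoEncoder",
    "IdentityExtractor",
    "RandomConvExtractor",
    "mse_loss",
    "perceptual_loss",
    "should_stop",
    "train",
    "TrainResult",
]


class ConvAutoEncoder:
    """Encoder/decoder pair defined by an :class:`AutoEncoderSpec`."""

    def __init__(self, spec: AutoEncoderSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        chans = spec.encoder_channels
        _, h, w = spec.input_shape
        self._bneck_hw = (h // 2**spec.n_blocks, w // 2**spec.n_blocks)
        self._bneck_c = chans[-1]

        enc: list[Layer] = []
        c_in = spec.input_shape[0]
        for i, c_out in enumerate(chans):
            enc.append(Conv2d(c_in, c_out, kernel=spec.kernel, stride=2, rng=rng))
            if i < spec.n_blocks - 1:  # last encoder conv stays linear
                enc += [BatchNorm2d(c_out), ReLU()]
            c_in = c_out
        self.encoder = Sequential(*enc)

        dec: list[Layer] = []
        dec_widths = chans[-2::-1] + [chans[0]]  # e.g. [256, 128, 64, 32, 32]
        c_in = chans[-1]
        for c_out in dec_widths:
            dec.append(UpsampleNearest2x())
            for _ in range(2):
                dec += [Conv2d(c_in, c_out, kernel=spec.kernel, stride=1, rng=rng),
                        BatchNorm2d(c_out), ReLU()]
                c_in = c_out
        dec.append(Conv2d(c_in, spec.input_shape[0], kernel=spec.kernel, stride=1, rng=rng))
        self.decoder = Sequential(*dec)

    # -- inference ---------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 4 or x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"expected batch of shape (B, {', '.join(map(str, self.spec.input_shape))}), "
                f"got {x.shape}"
            )
        return x

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Spectrogram batch ``(B, 1, H, W)`` → bottleneck embeddings ``(B, D)``."""
        x = self._check_input(x)
        h = self.encoder.forward(x, train=train)
        return h.reshape(len(h), -1)

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        """Bottleneck embeddings ``(B, D)`` → reconstructions ``(B, 1, H, W)``."""
        z = np.asarray(z, dtype=DTYPE)
        if z.ndim != 2 or z.shape[1] != self.spec.bottleneck_dim:
            raise ValueError(
                f"expected embeddings of shape (B, {self.spec.bottleneck_dim}), got {z.shape}"
            )
        hb, wb = self._bneck_hw
        h = z.reshape(len(z), self._bneck_c, hb, wb)
        return self.decoder.forward(h, train=train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.decode(self.encode(x, train=train), train=train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        # decoder input and encoder output share the (B, C, hb, wb) layout,
        # and the bottleneck flatten is a pure reshape, so gradients pass through
        g = self.decoder.backward(grad_out)
        return self.encoder.backward(g)

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- checkpointing -----------------------------------------------------

    def _state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for layer in self.encoder.layers + self.decoder.layers:
            if isinstance(layer, BatchNorm2d):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def save(self, path: str | Path) -> None:
        """Serialise weights + spec to a NumPy archive."""
        import dataclasses

        state = {f"a{i}": a for i, a in enumerate(self._state_arrays())}
        spec_json = json.dumps(dataclasses.asdict(self.spec))
        np.savez_compressed(path, _spec=np.frombuffer(spec_json.encode(), dtype=np.uint8),
                            **state)

    @classmethod
    def load(cls, path: str | Path) -> "ConvAutoEncoder":
        with np.load(path, allow_pickle=False) as archive:
            spec = AutoEncoderSpec(**json.loads(bytes(archive["_spec"]).decode()))
            model = cls(spec)
            for i, target in enumerate(model._state_arrays()):
                target[...] = archive[f"a{i}"]
        return model


# ---------------------------------------------------------------------------
# losses


def mse_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error over every spectro-temporal bin."""
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def _mse_grad(x: np.ndarray, x_hat: np.ndarray) -> tuple[float, np.ndarray]:
    diff = (x_hat - x).astype(DTYPE)
    return float(np.mean(diff.astype(np.float64) ** 2)), 2.0 * diff / diff.size


class _ExtractorBase:
    """Frozen convolutional feature extractor: ``layers`` + tap indices.

    ``taps`` are indices into ``layers``; the feature maps are the outputs
    of those layers (index ``-1`` taps the raw input).
    """

    layers: list[Layer]
    taps: list[int]

    def features(self, x: np.ndarray) -> list[np.ndarray]:
        """Feature maps of a batch of 1-channel images."""
        outs, h = [], np.asarray(x, dtype=DTYPE)
        if -1 in self.taps:
            outs.append(h)
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train=False)
            if i in self.taps:
                outs.append(h)
        return outs

    def loss_and_grad(self, x: np.ndarray, x_hat: np.ndarray) -> tuple[float, np.ndarray]:
        """Perceptual loss and its gradient with respect to ``x_hat``."""
        f_ref = self.features(x)
        acts, h = [], np.asarray(x_hat, dtype=DTYPE)
        for layer in self.layers:
            h = layer.forward(h, train=True)
            acts.append(h)
        taps = sorted(self.taps)
        n_maps = len(taps)
        loss = 0.0
        tap_grads: dict[int, np.ndarray] = {}
        ref_iter = iter(f_ref)
        for t in taps:
            f_hat = x_hat if t == -1 else acts[t]
            diff = f_hat - next(ref_iter)
            loss += float(np.mean(diff**2)) / n_maps
            tap_grads[t] = 2.0 * diff / diff.size / n_maps
        grad = np.zeros_like(acts[-1]) if self.layers else np.zeros_like(np.asarray(x_hat, DTYPE))
        for i in range(len(self.layers) - 1, -1, -1):
            if i in tap_grads:
                grad = grad + tap_grads[i]
            grad = self.layers[i].backward(grad)
        if -1 in tap_grads:
            grad = grad + tap_grads[-1]
        return loss, grad


class IdentityExtractor(_ExtractorBase):
    """Taps the raw image: the perceptual loss degenerates to plain MSE."""

    def __init__(self):
        self.layers = []
        self.taps = [-1]


class RandomConvExtractor(_ExtractorBase):
    """Seeded random-weight multi-scale convolutional filterbank.

    Three stride-2 3x3 convolution + ReLU stages (1 → 8 → 16 → 32 channels)
    with fixed He-initialised weights; feature maps are tapped after every
    ReLU.  Random convolutional features preserve local spectro-temporal
    structure at several scales, so matching them emphasises contours over
    diffuse background — the role a pretrained image network's activations
    play when one is available (plug one in through the same contract).
    """

    def __init__(self, seed: int = 0, channels: tuple[int, ...] = (8, 16, 32)):
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        taps = []
        c_in = 1
        for c_out in channels:
            layers.append(Conv2d(c_in, c_out, stride=2, rng=rng))
            layers.append(ReLU())
            taps.append(len(layers) - 1)
            c_in = c_out
        self.layers, self.taps = layers, taps


def perceptual_loss(x: np.ndarray, x_hat: np.ndarray, extractor: _ExtractorBase) -> float:
    """MSE between extractor feature maps of ``x`` and ``x_hat``, averaged over maps."""
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    f_x, f_hat = extractor.features(x), extractor.features(x_hat)
    vals = [np.mean((a - b) ** 2) for a, b in zip(f_x, f_hat)]
    if not all(np.isfinite(v) for v in vals):
        raise FloatingPointError("non-finite extractor activations")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# training


def should_stop(history, window: int = 1000) -> bool:
    """Stopping rule: the median loss of the last ``window`` steps did not
    decrease compared to the previous ``window`` steps.

    Returns ``False`` until ``2 * window`` steps exist.  Only the most
    recent ``2 * window`` values are ever consulted.
    """
    history = np.asarray(history, dtype=float)
    if history.size < 2 * window:
        return False
    last = history[-window:]
    prev = history[-2 * window : -window]
    return bool(np.median(last) >= np.median(prev))


@dataclass
class TrainResult:
    model: ConvAutoEncoder
    history: np.ndarray
    stopped_early: bool


def train(
    values: np.ndarray,
    spec: AutoEncoderSpec,
    config: TrainConfig,
    extractor: _ExtractorBase | None = None,
) -> TrainResult:
    """Train an auto-encoder on a stack of spectrograms.

    ``values`` is a ``(N, 1, H, W)`` array (or a ``SpectrogramBatch.values``).
    Batches are drawn by seeded shuffling, one Adam step per batch, until
    :func:`should_stop` fires or ``config.max_steps`` is reached.  All
    randomness (weight init, batch order) derives from ``config.seed``, so a
    run is reproducible on one machine.
    """
    x = np.asarray(values, dtype=DTYPE)
    if x.ndim != 4 or len(x) == 0:
        raise ValueError("expected a non-empty (N, 1, H, W) array of spectrograms")
    n = len(x)
    bs = min(config.batch_size, n)

    model = ConvAutoEncoder(spec, seed=config.seed)
    if config.loss == "perceptual" and extractor is None:
        extractor = RandomConvExtractor(seed=config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    history: list[float] = []
    order = np.empty(0, dtype=int)
    pos = 0
    for step in range(config.max_steps):
        if pos + bs > len(order):
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + bs]
        pos += bs
        xb = x[idx]
        opt.zero_grad()
        x_hat = model.forward(xb, train=True)
        if config.loss == "mse":
            loss, grad = _mse_grad(xb, x_hat)
        else:
            loss, grad = extractor.loss_and_grad(xb, x_hat)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss {loss} at step {step}; aborting training")
        model.backward(grad)
        opt.step()
        history.append(loss)
        if should_stop(history, config.window):
            return TrainResult(model, np.asarray(history), stopped_early=True)
    return TrainResult(model, np.asarray(history), stopped_early=False)
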