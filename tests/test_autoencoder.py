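"""Auto-encoder architecture, losses, stopping rule and training loop."""

import numpy as np
import pytest

import vocrep.nn as nn
from vocrep.autoencoder import (
    ConvAutoEncoder,
    IdentityExtractor,
    RandomConvExtractor,
    mse_loss,
    perceptual_loss,
    should_stop,
    train,
)
from vocrep.config import AutoEncoderSpec, TrainConfig


@pytest.fixture(scope="module")
def default_model():
    return ConvAutoEncoder(AutoEncoderSpec(), seed=0)


class TestArchitecture:
    def test_encode_shape_default(self, default_model, rng):
        x = rng.normal(size=(2, 1, 128, 128))
        z = default_model.encode(x)
        assert z.shape == (2, 256)

    def test_decode_restores_input_shape(self, default_model, rng):
        z = rng.normal(size=(2, 256))
        assert default_model.decode(z).shape == (2, 1, 128, 128)

    def test_roundtrip_finite(self, default_model, rng):
        x = rng.normal(size=(2, 1, 128, 128))
        out = default_model.decode(default_model.encode(x))
        assert out.shape == x.shape
        assert np.isfinite(out).all()

    def test_five_stride2_halvings(self, default_model, rng):
        h = rng.normal(size=(1, 1, 128, 128)).astype(np.float32)
        sizes = []
        for layer in default_model.encoder.layers:
            h = layer.forward(h)
            if isinstance(layer, nn.Conv2d):
                sizes.append(h.shape[-1])
        assert sizes == [64, 32, 16, 8, 4]

    @pytest.mark.parametrize(
        "shape, bottleneck",
        [((1, 64, 64), 64), ((1, 32, 32), 32), ((1, 128, 64), 128)],
    )
    def test_k_2n_variants_are_shape_inverse(self, shape, bottleneck, rng):
        spec = AutoEncoderSpec(base_channels=2, bottleneck_dim=bottleneck,
                               input_shape=shape)
        model = ConvAutoEncoder(spec, seed=1)
        x = rng.normal(size=(3, *shape))
        z = model.encode(x)
        assert z.shape == (3, bottleneck)
        assert model.decode(z).shape == (3, *shape)

    def test_non_divisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            AutoEncoderSpec(input_shape=(1, 100, 128))

    def test_wrong_input_shape_names_dims(self, default_model):
        with pytest.raises(ValueError, match=r"1, 128, 128"):
            default_model.encode(np.zeros((2, 1, 64, 64)))

    def test_wrong_embedding_width_rejected(self, default_model):
        with pytest.raises(ValueError, match="256"):
            default_model.decode(np.zeros((2, 100)))

    def test_inference_determinism(self, default_model, rng):
        x = rng.normal(size=(1, 1, 128, 128))
        pair = np.concatenate([x, x])
        z = default_model.encode(pair)
        np.testing.assert_array_equal(z[0], z[1])

    def test_parameter_count_is_function_of_spec(self):
        # regression values: recomputed counts for the default and a reduced spec
        assert ConvAutoEncoder(AutoEncoderSpec(), seed=0).n_parameters() == 1_654_769
        small = AutoEncoderSpec(base_channels=4, bottleneck_dim=256)
        assert (ConvAutoEncoder(small, seed=0).n_parameters()
                == ConvAutoEncoder(small, seed=99).n_parameters())

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        spec = AutoEncoderSpec(base_channels=2, bottleneck_dim=32, input_shape=(1, 32, 32))
        model = ConvAutoEncoder(spec, seed=3)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = ConvAutoEncoder.load(path)
        x = rng.normal(size=(4, 1, 32, 32))
        np.testing.assert_array_equal(model.encode(x), clone.encode(x))


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, monkeypatch, rng):
        monkeypatch.setattr(nn, "DTYPE", np.float64)
        net = nn.Sequential(
            nn.Conv2d(2, 3, stride=2, rng=rng), nn.BatchNorm2d(3), nn.ReLU(),
            nn.UpsampleNearest2x(), nn.Conv2d(3, 1, stride=1, rng=rng),
        )
        x = rng.normal(size=(4, 2, 8, 8))

        def objective(xv):
            return 0.5 * np.sum(net.forward(xv, train=True) ** 2)

        out = net.forward(x, train=True)
        for p in net.params():
            p.grad[...] = 0
        gx = net.backward(out)
        eps = 1e-6
        for index in [(0, 1, 3, 2), (2, 0, 5, 7), (3, 1, 0, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[index] += eps
            xm[index] -= eps
            numeric = (objective(xp) - objective(xm)) / (2 * eps)
            assert numeric == pytest.approx(gx[index], rel=1e-4, abs=1e-7)


class TestLosses:
    def test_mse_zero_for_identical(self, rng):
        x = rng.normal(size=(2, 1, 8, 8))
        assert mse_loss(x, x) == 0.0

    def test_mse_closed_form(self):
        assert mse_loss(np.zeros((2, 1, 4, 4)), np.ones((2, 1, 4, 4))) == 1.0

    def test_mse_matches_elementwise_loop(self, rng):
        x, y = rng.normal(size=(2, 3, 4, 5)), rng.normal(size=(2, 3, 4, 5))
        brute = np.mean([(a - b) ** 2 for a, b in zip(x.ravel(), y.ravel())])
        assert mse_loss(x, y) == pytest.approx(brute, rel=1e-12)

    def test_mse_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 8, 8)))

    def test_perceptual_zero_at_identity(self, rng):
        x = rng.normal(size=(2, 1, 32, 32))
        assert perceptual_loss(x, x, RandomConvExtractor(seed=0)) == 0.0

    def test_perceptual_symmetry(self, rng):
        ext = RandomConvExtractor(seed=0)
        x, y = rng.normal(size=(2, 1, 32, 32)), rng.normal(size=(2, 1, 32, 32))
        assert perceptual_loss(x, y, ext) == pytest.approx(perceptual_loss(y, x, ext))

    def test_identity_extractor_equals_mse(self, rng):
        x, y = rng.normal(size=(2, 1, 16, 16)), rng.normal(size=(2, 1, 16, 16))
        assert perceptual_loss(x, y, IdentityExtractor()) == pytest.approx(
            mse_loss(x, y), rel=1e-5
        )

    def test_extractor_loss_grad_matches_loss(self, rng):
        ext = RandomConvExtractor(seed=1)
        x, y = rng.normal(size=(2, 1, 32, 32)), rng.normal(size=(2, 1, 32, 32))
        loss, grad = ext.loss_and_grad(x, y)
        assert loss == pytest.approx(perceptual_loss(x, y, ext), rel=1e-5)
        assert grad.shape == y.shape


class TestStoppingRule:
    def test_false_on_strictly_decreasing(self):
        assert not should_stop(np.linspace(2.0, 1.0, 2000), window=1000)

    def test_true_on_plateau(self):
        assert should_stop(np.ones(2000), window=1000)

    def test_false_while_median_still_decreasing(self):
        history = np.concatenate([np.full(1000, 1.0), np.full(1000, 0.9)])
        assert not should_stop(history, window=1000)

    def test_false_before_two_windows(self):
        assert not should_stop(np.ones(1999), window=1000)

    def test_ignores_history_older_than_two_windows(self, rng):
        recent = np.concatenate([np.full(50, 1.0), np.full(50, 0.5)])
        noise = rng.uniform(0, 100, size=500)
        assert should_stop(recent, window=50) == should_stop(
            np.concatenate([noise, recent]), window=50
        )


@pytest.fixture(scope="module")
def toy_batch():
    # two synthetic spectro-like patterns + noise, 32x32
    rng = np.random.default_rng(0)
    x = rng.normal(0, 0.3, size=(40, 1, 32, 32))
    x[:20, 0, 8:12, :] += 3.0   # horizontal band
    x[20:, 0, :, 14:18] += 3.0  # vertical band
    return x


@pytest.fixture(scope="module")
def toy_spec():
    return AutoEncoderSpec(base_channels=4, bottleneck_dim=32,
                           input_shape=(1, 32, 32))


class TestTraining:

    def test_loss_decreases(self, toy_batch, toy_spec):
        cfg = TrainConfig(batch_size=16, loss="mse", seed=0, max_steps=120)
        result = train(toy_batch, toy_spec, cfg)
        h = result.history
        assert np.median(h[-len(h) // 4 :]) < np.median(h[: len(h) // 4])

    def test_same_seed_identical_histories(self, toy_batch, toy_spec):
        cfg = TrainConfig(batch_size=16, loss="mse", seed=5, max_steps=20)
        h1 = train(toy_batch, toy_spec, cfg).history
        h2 = train(toy_batch, toy_spec, cfg).history
        np.testing.assert_array_equal(h1, h2)

    def test_both_losses_run_to_termination(self, toy_batch, toy_spec):
        for loss in ("mse", "perceptual"):
            cfg = TrainConfig(batch_size=16, loss=loss, seed=0, max_steps=10)
            result = train(toy_batch, toy_spec, cfg)
            assert len(result.history) == 10
            assert np.isfinite(result.history).all()

    def test_stopping_rule_fires_on_plateau(self, toy_batch, toy_spec):
        # a tiny window makes the plateau criterion reachable quickly
        cfg = TrainConfig(batch_size=16, loss="mse", seed=0, max_steps=500, window=5)
        result = train(toy_batch, toy_spec, cfg)
        assert result.stopped_early
        assert len(result.history) < 500

    def test_embeddings_linearly_separable_by_type(self, toy_batch, toy_spec):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        cfg = TrainConfig(batch_size=16, loss="mse", seed=0, max_steps=120)
        result = train(toy_batch, toy_spec, cfg)
        z = result.model.encode(toy_batch)
        y = np.repeat([0, 1], 20)
        probe = LogisticRegression(max_iter=2000)
        accuracy = cross_val_score(probe, z, y, cv=4).mean()
        assert accuracy > 0.95
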