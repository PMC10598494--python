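"""3D classifier: pooling oracles, architecture contracts, training mechanics."""

import numpy as np
import pytest

from ctmonitor import synthgen as sg
from ctmonitor.frame_predictor import TrainConfig
from ctmonitor.nn.model import EarlyStopPolicy
from ctmonitor.preprocess import PreprocConfig
from ctmonitor.volume_classifier import (
    VolumeClassifierSpec,
    build_volume_classifier,
    global_average_pool,
    max_pool_3d,
    predict_volume,
    prepare_volume_dataset,
    train_volume_classifier,
    volumes_to_tensor,
)


def brute_force_max_pool(x, window, stride):
    """Triple-loop oracle."""
    kd, kh, kw = window
    sd, sh, sw = stride
    d = (x.shape[0] - kd) // sd + 1
    h = (x.shape[1] - kh) // sh + 1
    w = (x.shape[2] - kw) // sw + 1
    out = np.empty((d, h, w))
    for i in range(d):
        for j in range(h):
            for k in range(w):
                out[i, j, k] = x[i * sd : i * sd + kd,
                                 j * sh : j * sh + kh,
                                 k * sw : k * sw + kw].max()
    return out


class TestMaxPool3D:
    def test_constant_map(self):
        out = max_pool_3d(np.full((4, 4, 4), 2.5), (2, 2, 2))
        assert out.shape == (2, 2, 2)
        np.testing.assert_array_equal(out, 2.5)

    def test_block_of_one_to_eight(self):
        x = np.arange(1.0, 9.0).reshape(2, 2, 2)
        assert max_pool_3d(x, (2, 2, 2))[0, 0, 0] == 8.0

    def test_matches_brute_force_on_many_random_maps(self, rng):
        for _ in range(100):
            x = rng.normal(size=(5, 6, 7))
            window = tuple(rng.integers(1, 4, size=3))
            stride = tuple(rng.integers(1, 3, size=3))
            np.testing.assert_array_equal(
                max_pool_3d(x, window, stride),
                brute_force_max_pool(x, window, stride))

    def test_output_dims_formula(self, rng):
        out = max_pool_3d(rng.normal(size=(7, 9, 11)), (2, 3, 4), 2)
        assert out.shape == ((7 - 2) // 2 + 1, (9 - 3) // 2 + 1, (11 - 4) // 2 + 1)

    def test_window_too_large(self, rng):
        with pytest.raises(ValueError, match="window"):
            max_pool_3d(rng.normal(size=(3, 3, 3)), (4, 2, 2))


class TestGlobalAveragePool:
    def test_uniform_map(self):
        out = global_average_pool(np.full((3, 3, 4), 1.5))
        np.testing.assert_array_equal(out, np.full((1, 4), 1.5))

    def test_small_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(2, 2, 1)
        assert global_average_pool(x)[0, 0] == 2.5

    def test_output_length_is_channel_count(self, rng):
        for m, n in [(2, 3), (5, 1), (4, 7)]:
            assert global_average_pool(rng.normal(size=(m, m, n))).shape == (1, n)

    def test_matches_mean_oracle(self, rng):
        x = rng.normal(size=(3, 4, 5, 6))
        np.testing.assert_allclose(global_average_pool(x)[0],
                                   [x[..., c].mean() for c in range(6)])


class TestArchitecture:
    def test_shape_and_range(self, rng):
        model = build_volume_classifier(VolumeClassifierSpec.desk_scale(16), seed=0)
        out = model.forward(rng.random((2, 16, 16, 16, 1)))
        assert out.shape == (2, 1)
        assert np.all((out >= 0.0) & (out <= 1.0))

    def test_first_conv_parameter_count(self):
        """3*3*3*1*64 weights + 64 biases = 1,792 parameters."""
        model = build_volume_classifier(VolumeClassifierSpec(), seed=0)
        assert model.layers[0].n_params() == 3 * 3 * 3 * 1 * 64 + 64 == 1792

    def test_four_pools_shrink_sixteenfold(self, rng):
        model = build_volume_classifier(
            VolumeClassifierSpec(input_size=(64, 64, 64), filters=(2, 2, 2, 2),
                                 dense_units=4), seed=0)
        # feature map just before global pooling: 64 / 2^4 = 4 per axis
        x = rng.random((1, 64, 64, 64, 1))
        out = x
        for layer in model.layers[:-4]:
            out = layer.forward(out)
        assert out.shape[1:4] == (4, 4, 4)

    def test_too_small_input_names_minimum(self):
        with pytest.raises(ValueError, match="at least 16"):
            build_volume_classifier(VolumeClassifierSpec(input_size=(8, 8, 8)))


@pytest.fixture(scope="module")
def tiny_setup():
    data = sg.generate_labeled_volumes(12, 0.5, size=(16, 16, 16), seed=2)
    x, y = prepare_volume_dataset(data, PreprocConfig(target_size=(16, 16, 16)))
    return x, y


class TestTraining:

    def test_single_class_rejected(self, tiny_setup):
        x, y = tiny_setup
        model = build_volume_classifier(VolumeClassifierSpec.desk_scale(16), seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_volume_classifier(model, (x, np.zeros_like(y)))

    def test_constant_metric_stops_after_patience_plus_one(self, rng):
        # a stateless model at zero learning rate keeps val_loss exactly constant
        from ctmonitor import nn

        x = rng.random((10, 4))
        y = (rng.random((10, 1)) > 0.5).astype(float)
        model = nn.Model([nn.Dense(1, activation="sigmoid")], input_shape=(4,), seed=0)
        history = model.fit(
            x, y, epochs=50, batch_size=5, loss="bce", metric="binary_accuracy",
            optimizer=nn.Adam(0.0), validation_split=0.2,
            early_stopping=EarlyStopPolicy(monitor="val_loss", patience=3))
        assert len(history) == 4

    def test_early_stopping_restores_best(self, tiny_setup):
        x, y = tiny_setup
        model = build_volume_classifier(VolumeClassifierSpec.desk_scale(16), seed=1)
        stop = EarlyStopPolicy(monitor="val_loss", patience=2, restore_best=True)
        history = train_volume_classifier(
            model, (x, y), TrainConfig(epochs=8, learning_rate=3e-3), stop=stop)
        if len(history) < 8:  # stopped early: restored weights = best epoch
            pv = model.predict(x)
            assert np.isfinite(pv).all()
        assert min(history.val_loss) <= history.val_loss[-1] + 1e-12

    def test_shuffling_preserves_sample_multiset(self, rng):
        """Epoch shuffling permutes batches but never drops or duplicates."""
        from ctmonitor import nn

        seen = []

        class Spy(nn.Layer):
            def forward(self, x, training=False):
                if training:
                    seen.append(x.sum(axis=1))
                return x

            def backward(self, dy):
                return dy

        x = rng.random((10, 3))
        y = (rng.random((10, 1)) > 0.5).astype(float)
        model = nn.Model([Spy(), nn.Dense(1, activation="sigmoid")],
                         input_shape=(3,), seed=0)
        model.fit(x, y, epochs=2, batch_size=3, loss="bce",
                  metric="binary_accuracy", validation_split=0.0)
        per_epoch = np.array_split(np.concatenate(seen), 2)
        ref = np.sort(x.sum(axis=1))
        for ep in per_epoch:
            np.testing.assert_allclose(np.sort(ep), ref)


class TestInference:
    def test_predict_volume_deterministic_with_dropout_layer(self, rng):
        model = build_volume_classifier(VolumeClassifierSpec.desk_scale(16), seed=0)
        vol = rng.random((16, 16, 16))
        p1 = predict_volume(model, vol)
        p2 = predict_volume(model, vol)
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0

    def test_predict_volume_shape_check(self, rng):
        model = build_volume_classifier(VolumeClassifierSpec.desk_scale(16), seed=0)
        with pytest.raises(ValueError, match="does not match"):
            predict_volume(model, rng.random((8, 8, 8)))

    def test_volumes_to_tensor_axis_adapter(self):
        v = np.zeros((3, 4, 5))  # (depth, height, width)
        t = volumes_to_tensor([v])
        assert t.shape == (1, 5, 4, 3, 1)  # (n, width, height, depth, 1)
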