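"""CNN architecture arithmetic, augmentation, training loop, thresholding."""

import numpy as np
import pytest

from hsinuclei.cnn import (
    CNNConfig,
    LeakageError,
    augment_eval,
    augment_train,
    build_model,
    output_shapes,
    predict_proba,
    select_threshold,
    train,
)

#: The published feature-map chain (channel count of the second pool
#: corrected to its input's 768; pooling cannot change channels).
EXPECTED_CHAIN = [
    ("input", (101, 101, None)),
    ("conv1", (97, 97, 256)),
    ("conv2", (95, 95, 256)),
    ("maxpool_after_conv2", (47, 47, 256)),
    ("conv3", (45, 45, 384)),
    ("conv4", (43, 43, 512)),
    ("conv5", (41, 41, 768)),
    ("maxpool_after_conv5", (21, 21, 768)),
    ("conv6", (19, 19, 768)),
    ("conv7", (17, 17, 1024)),
    ("conv8", (15, 15, 1536)),
    ("conv9", (13, 13, 2048)),
    ("global_average_pool", (1, 1, 2048)),
    ("dense_relu", (1, 1, 2048)),
    ("dense_sigmoid", (1, 1, 1)),
]


def tiny_config(**kw):
    """A small architecture for fast training-loop tests."""
    defaults = dict(
        input_channels=4, patch_size=15, kernel_sizes=(3, 3), filters=(6, 6),
        pool_after=((0, False),), dense_units=8, dropout_range=(0.0, 0.0),
        kernel_init="he_normal", learning_rate=1e-2, batch_size=8,
        max_epochs=3, patience=3, seed=0, allow_any_channels=True,
    )
    defaults.update(kw)
    return CNNConfig(**defaults)


class TestShapeChain:
    @pytest.mark.parametrize("channels", [3, 87])
    def test_published_chain_reproduced(self, channels):
        chain = output_shapes(CNNConfig(input_channels=channels))
        assert len(chain) == len(EXPECTED_CHAIN)
        for (name, shape), (exp_name, exp_shape) in zip(chain, EXPECTED_CHAIN):
            assert name == exp_name
            if exp_shape[2] is None:
                assert shape == (101, 101, channels)
            else:
                assert shape == exp_shape

    def test_first_conv_output_97x97x256(self):
        chain = dict(output_shapes(CNNConfig(input_channels=87)))
        assert chain["conv1"] == (97, 97, 256)

    def test_width_multiplier_scales_channels_not_space(self):
        chain = dict(output_shapes(CNNConfig(input_channels=87,
                                             width_multiplier=1 / 32)))
        assert chain["conv1"] == (97, 97, 8)
        assert chain["conv9"][:2] == (13, 13)

    def test_actual_forward_matches_arithmetic(self, rng):
        """A real forward pass at reduced width hits every predicted size."""
        from hsinuclei.cnn import Conv2D, MaxPool2

        cfg = CNNConfig(input_channels=3, width_multiplier=1 / 64, seed=0)
        model = build_model(cfg)
        expected = [s for name, s in output_shapes(cfg)
                    if name.startswith(("conv", "maxpool"))]
        out = rng.random((1, 101, 101, 3)).astype(np.float32)
        seen = []
        for layer in model.layers:
            out = layer.forward(out, False)
            if isinstance(layer, (Conv2D, MaxPool2)):
                seen.append(out.shape[1:])
        assert seen == expected

    def test_unusual_channel_count_needs_override(self):
        with pytest.raises(ValueError):
            build_model(CNNConfig(input_channels=7))
        build_model(tiny_config(input_channels=7))  # override path works


class TestForward:
    def test_zero_patch_gives_probability_in_open_interval(self):
        model = build_model(tiny_config())
        p = model.predict_proba_batch(np.zeros((2, 15, 15, 4), dtype=np.float32))
        assert np.isfinite(p).all()
        assert ((p > 0) & (p < 1)).all()


class TestAugmentation:
    def test_train_augmentation_quadruples(self, rng):
        patches = rng.random((5, 9, 9, 2))
        labels = np.arange(5)
        out, lab = augment_train(patches, labels)
        assert out.shape == (20, 9, 9, 2)
        assert lab.tolist() == list(range(5)) * 4

    def test_rotations_preserve_pixel_multisets(self, rng):
        patch = rng.random((1, 7, 7, 1))
        out = augment_train(patch)
        for k in range(4):
            np.testing.assert_allclose(np.sort(out[k].ravel()),
                                       np.sort(patch[0].ravel()))
            np.testing.assert_allclose(out[k], np.rot90(patch[0], k, axes=(0, 1)))

    def test_symmetric_patch_views_identical(self):
        patch = np.ones((6, 6, 3)) * 0.3
        out = augment_train(patch[None])
        assert all(np.array_equal(out[0], out[k]) for k in range(4))
        views = augment_eval(patch)
        assert views.shape == (4, 6, 6, 3)
        assert all(np.array_equal(views[0], v) for v in views)

    def test_eval_views_are_the_declared_quartet(self, rng):
        patch = rng.random((5, 5, 2))
        views = augment_eval(patch)
        np.testing.assert_array_equal(views[0], patch)
        np.testing.assert_array_equal(views[1], np.rot90(patch, 1, axes=(0, 1)))
        np.testing.assert_array_equal(views[2], patch[:, ::-1])
        np.testing.assert_array_equal(views[3], patch[::-1, :])

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_train(rng.random((2, 4, 6, 1)))
        with pytest.raises(ValueError):
            augment_eval(rng.random((4, 6, 1)))

    def test_tta_mean_of_constant_model_is_constant(self, rng):
        """Averaging views of a rotation-invariant predictor changes nothing."""
        model = build_model(tiny_config(seed=3))
        sym = np.tile(rng.random((1, 1, 1, 4)), (3, 15, 15, 1)).astype(np.float32)
        single = model.predict_proba_batch(sym)
        averaged = predict_proba(model, sym, tta=True)
        np.testing.assert_allclose(averaged, single, atol=1e-6)


def _toy_data(rng, n=24, size=15, channels=4, shift=2.0):
    x = rng.random((n, size, size, channels)).astype(np.float32)
    y = (np.arange(n) % 2).astype(np.float32)
    x[y > 0.5, :, :, 0] += shift  # strong channel-0 offset for class 1
    return x, y


class TestTrainingLoop:
    def test_patient_overlap_raises(self, rng):
        model = build_model(tiny_config())
        x, y = _toy_data(rng)
        with pytest.raises(LeakageError):
            train(model, x, y, x, y, train_patients={"A", "B"},
                  val_patients={"B", "C"})

    def test_zero_learning_rate_freezes_loss(self, rng):
        model = build_model(tiny_config(learning_rate=0.0, max_epochs=3))
        x, y = _toy_data(rng)
        history = train(model, x[:16], y[:16], x[16:], y[16:], augment=False)
        losses = [h["train_loss"] for h in history]
        # identical up to float32 batch-summation order
        assert losses[0] == pytest.approx(losses[-1], abs=1e-5)

    def test_same_seed_identical_histories(self, rng):
        x, y = _toy_data(rng)
        runs = []
        for _ in range(2):
            model = build_model(tiny_config(seed=11, max_epochs=3))
            runs.append(train(model, x[:16], y[:16], x[16:], y[16:],
                              augment=True))
        assert runs[0] == runs[1]

    def test_learns_separable_toy_task(self, rng):
        x, y = _toy_data(rng, n=32)
        model = build_model(tiny_config(max_epochs=15, patience=15))
        history = train(model, x[:24], y[:24], x[24:], y[24:], augment=False)
        assert max(h["val_accuracy"] for h in history) >= 0.9


def test_checkpoint_round_trip(tmp_path, rng):
    """Saved weights + architecture JSON restore an identical predictor."""
    from hsinuclei.cnn import Model

    model = build_model(tiny_config(seed=5))
    x = rng.random((3, 15, 15, 4)).astype(np.float32)
    model.save(tmp_path / "ckpt")
    back = Model.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(back.predict_proba_batch(x),
                                  model.predict_proba_batch(x))


class TestSelectThreshold:
    def test_separable_scores_give_midpoint(self):
        thr = select_threshold([0.1, 0.2, 0.8, 0.9],
                               [False, False, True, True])
        assert thr == pytest.approx(0.5)

    def test_uninformative_scores_fall_back_with_warning(self):
        with pytest.warns(UserWarning):
            thr = select_threshold([0.4, 0.4, 0.4, 0.4],
                                   [True, False, True, False])
        assert thr == 0.5

    def test_matches_exhaustive_sweep_oracle(self):
        scores = np.array([0.15, 0.3, 0.45, 0.55, 0.7, 0.85])
        truths = np.array([False, False, True, False, True, True])
        thr = select_threshold(scores, truths)

        def youden(cut):
            called = scores >= cut
            sens = (called & truths).sum() / truths.sum()
            spec = (~called & ~truths).sum() / (~truths).sum()
            return sens + spec - 1

        sweep = [(youden(c), c) for c in np.linspace(0, 1, 2001)]
        best_j = max(j for j, _ in sweep)
        assert youden(thr) == pytest.approx(best_j)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.2, 0.8], [True, True])
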