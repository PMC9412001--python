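"""Batching, fold splitting, and the training loop's bookkeeping."""

import numpy as np
import pytest

from lesionseg.synthetic import PhantomParams, generate_phantom_pair
from lesionseg.training import (FoldModels, LossConfig, TrainConfig,
                                extract_slice, make_batches, train_folds,
                                total_loss, total_loss_grad)
from lesionseg.unet import UNet2D, UNetConfig
from lesionseg.preprocessing import preprocess_pair, PreprocessConfig


@pytest.fixture(scope="module")
def tiny_subjects():
    """Three preprocessed 32-cube subjects."""
    cfg = PreprocessConfig(cube_size=32)
    out = []
    for s in range(3):
        pair, gt, _ = generate_phantom_pair(PhantomParams(seed=200 + s))
        cube_pair, cube_masks = preprocess_pair(pair, [gt], cfg)
        out.append((cube_pair, cube_masks[0]))
    return out


class TestExtractSlice:
    def test_orientation_axes(self, rng):
        vol = rng.normal(size=(4, 5, 6))
        np.testing.assert_array_equal(extract_slice(vol, "sagittal", 2),
                                      vol[2])
        np.testing.assert_array_equal(extract_slice(vol, "coronal", 3),
                                      vol[:, 3])
        np.testing.assert_array_equal(extract_slice(vol, "axial", 4),
                                      vol[:, :, 4])


class TestMakeBatches:
    def test_batch_size_is_twenty_by_default(self, tiny_subjects):
        cfg = TrainConfig()
        x, y = next(make_batches(tiny_subjects, cfg, seed=0, n_batches=1))
        assert x.shape == (20, 2, 32, 32)
        assert y.shape == (20, 32, 32)

    def test_same_seed_same_sequence(self, tiny_subjects):
        cfg = TrainConfig()
        a = [x for x, _ in make_batches(tiny_subjects, cfg, 7, n_batches=3)]
        b = [x for x, _ in make_batches(tiny_subjects, cfg, 7, n_batches=3)]
        for xa, xb in zip(a, b):
            np.testing.assert_array_equal(xa, xb)

    def test_different_seeds_differ(self, tiny_subjects):
        cfg = TrainConfig()
        xa, _ = next(make_batches(tiny_subjects, cfg, 7, n_batches=1))
        xb, _ = next(make_batches(tiny_subjects, cfg, 8, n_batches=1))
        assert not np.array_equal(xa, xb)

    def test_single_slice_subject_repeats_permitted(self, tiny_subjects):
        # a single subject still fills a 20-slice batch via repeats
        cfg = TrainConfig()
        x, _ = next(make_batches(tiny_subjects[:1], cfg, 0, n_batches=1))
        assert x.shape[0] == 20

    def test_empty_subject_list_rejected(self):
        with pytest.raises(ValueError):
            next(make_batches([], TrainConfig(), 0))

    def test_every_orientation_contributes_over_an_epoch(self, tiny_subjects):
        # the orientation of each drawn slice is not recorded in the batch,
        # so check via the sampler's own distribution: over many draws all
        # three slicing axes must appear (statistically certain)
        cfg = TrainConfig(steps_per_epoch=None)
        batches = list(make_batches(tiny_subjects, cfg, seed=3))
        n_default = int(np.ceil(len(tiny_subjects) * 3 * 32 / 20))
        assert len(batches) == n_default

    def test_foreground_oversampling_increases_lesion_voxels(self,
                                                             tiny_subjects):
        plain = TrainConfig(foreground_slice_fraction=0.0)
        boosted = TrainConfig(foreground_slice_fraction=0.9)
        n_plain = sum(y.sum() for _, y in
                      make_batches(tiny_subjects, plain, 5, n_batches=10))
        n_boost = sum(y.sum() for _, y in
                      make_batches(tiny_subjects, boosted, 5, n_batches=10))
        assert n_boost > n_plain


class TestTrainFolds:
    def test_returns_requested_fold_count_and_holdouts(self, tiny_subjects):
        cfg = TrainConfig(n_folds=2, max_epochs=1, steps_per_epoch=2,
                          holdout_fraction=0.34, seed=0)
        fm = train_folds(tiny_subjects, cfg, LossConfig(k_percent=50),
                         UNetConfig(base_channels=2, depth=2, slice_size=32))
        assert isinstance(fm, FoldModels)
        assert len(fm.models) == 2
        # round(0.34 * 3) = 1 held-out subject per fold
        assert all(len(v) == 1 for v in fm.fold_assignments.values())
        assert {h["fold"] for h in fm.history} == {0, 1}

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_folds([], TrainConfig(), LossConfig(), UNetConfig())

    def test_history_records_losses_and_lr(self, tiny_subjects):
        cfg = TrainConfig(n_folds=1, max_epochs=2, steps_per_epoch=2, seed=1)
        fm = train_folds(tiny_subjects, cfg, LossConfig(k_percent=50),
                         UNetConfig(base_channels=2, depth=2, slice_size=32))
        for h in fm.history:
            assert {"fold", "epoch", "train_loss", "val_loss", "lr"} <= set(h)
            assert np.isfinite(h["train_loss"])


class TestEngineGradients:
    def test_full_network_gradient_matches_finite_differences(self, rng):
        """End-to-end double-precision gradient check through every layer
        type (conv, batchnorm, pooling, transpose conv, skip concat)."""
        net = UNet2D(UNetConfig(base_channels=4, depth=3, slice_size=16),
                     seed=0)
        for layer in net.layers():
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(np.float64)
            layer.grads = {k: np.zeros_like(v)
                           for k, v in layer.params.items()}
        x = rng.normal(size=(2, 2, 16, 16))
        y = (rng.random((2, 16, 16)) < 0.2).astype(float)
        g = np.stack([1 - y, y], axis=1)
        lc = LossConfig(k_percent=50)
        p = net.forward(x, train=True)
        net.backward(total_loss_grad(p, g, lc, class_axis=1))
        eps = 1e-6
        probes = [(net.enc_blocks[0][0], "W", (3, 7)),
                  (net.enc_blocks[0][1], "gamma", (2,)),
                  (net.ups[0], "W", (0, 1, 1, 0)),
                  (net.dec_blocks[1][3], "W", (3, 10)),
                  (net.head, "W", (1, 3))]
        for layer, key, idx in probes:
            analytic = layer.grads[key][idx]
            w0 = layer.params[key][idx]
            layer.params[key][idx] = w0 + eps
            lp = total_loss(net.forward(x, train=True), g, lc, class_axis=1)
            layer.params[key][idx] = w0 - eps
            lm = total_loss(net.forward(x, train=True), g, lc, class_axis=1)
            layer.params[key][idx] = w0
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - analytic) / max(abs(fd), 1e-10) < 1e-4
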