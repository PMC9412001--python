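"""Preprocessing chain: registration, cropping, resampling, augmentation."""

import numpy as np
import pytest

from lesionseg.preprocessing import (AugmentConfig, CropError,
                                     PreprocessConfig, RegistrationError,
                                     augment, crop_to_brain, estimate_affine,
                                     preprocess_pair, zscore)
from lesionseg.volume_io import BinaryMask3D, VolumePair

from .conftest import make_volume
from .oracles import flood_fill_components


def ellipsoid_volume(shape=(40, 40, 40), center=None, semi=(12, 10, 9),
                     noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    c = center or [s // 2 for s in shape]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r = sum(((g - ci) / si) ** 2 for g, ci, si in zip(grids, c, semi))
    data = np.where(r <= 1.0, 1.0, 0.0) + rng.normal(0, noise, shape)
    return make_volume(data.astype(np.float32))


class TestCrop:
    def test_box_tightly_encloses_ellipsoid_plus_margin(self):
        vol = ellipsoid_volume(center=(20, 18, 22), semi=(8, 6, 7))
        cropped, box = crop_to_brain(vol, margin=2)
        # painted extents: center ± semi, then ± margin
        for ax, (c, s) in enumerate(zip((20, 18, 22), (8, 6, 7))):
            assert box[ax].start == pytest.approx(c - s - 2, abs=1)
            assert box[ax].stop == pytest.approx(c + s + 1 + 2, abs=1)

    def test_all_foreground_identity_crop(self):
        vol = make_volume(np.concatenate([np.full((4, 8, 8), 5.0),
                                          np.full((4, 8, 8), 1.0)]))
        cropped, box = crop_to_brain(vol, margin=0)
        # Otsu splits the two plateaus; the bright half is kept
        assert cropped.shape[1:] == (8, 8)

    def test_constant_volume_raises(self):
        with pytest.raises(CropError):
            crop_to_brain(make_volume(np.zeros((8, 8, 8))))


class TestPreprocessPair:
    def _pair_with_mask(self, cube=32):
        base = ellipsoid_volume(seed=1)
        fup = ellipsoid_volume(seed=2)
        mask = np.zeros(fup.shape, dtype=np.uint8)
        mask[18:22, 18:21, 18:22] = 1
        return (VolumePair(base, fup),
                [BinaryMask3D.from_reference(mask, fup)],
                PreprocessConfig(cube_size=cube))

    def test_outputs_on_cube_grid(self):
        pair, masks, cfg = self._pair_with_mask(cube=32)
        out_pair, out_masks = preprocess_pair(pair, masks, cfg)
        assert out_pair.shape == (32, 32, 32)
        assert out_masks[0].shape == (32, 32, 32)

    def test_images_are_zscored(self):
        pair, masks, cfg = self._pair_with_mask()
        out_pair, _ = preprocess_pair(pair, masks, cfg)
        for v in (out_pair.baseline, out_pair.followup):
            assert abs(float(v.data.mean())) < 1e-5
            assert float(v.data.std()) == pytest.approx(1.0, abs=1e-5)

    def test_masks_stay_binary(self):
        pair, masks, cfg = self._pair_with_mask()
        _, out_masks = preprocess_pair(pair, masks, cfg)
        assert set(np.unique(out_masks[0].data)) <= {0, 1}

    def test_single_component_preserved_under_upsampling(self):
        pair, masks, cfg = self._pair_with_mask(cube=64)  # ~2x upsampling
        _, out_masks = preprocess_pair(pair, masks, cfg)
        comps = flood_fill_components(out_masks[0].data, 26)
        assert len(comps) == 1

    def test_zscore_idempotent_up_to_tolerance(self, rng):
        x = rng.normal(2.0, 3.0, size=(10, 10, 10))
        z1 = zscore(x)
        z2 = zscore(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)


class TestEstimateAffine:
    def test_self_registration_is_identity(self):
        vol = ellipsoid_volume()
        t = estimate_affine(vol, vol)
        assert np.abs(t - np.eye(4)).max() < 1e-3

    def test_known_translation_recovered(self):
        fixed = ellipsoid_volume(center=(20, 20, 20), noise=0.01)
        moving = ellipsoid_volume(center=(23, 20, 18), noise=0.01, seed=3)
        t = estimate_affine(moving, fixed)
        # mapping template voxel -> moving voxel: offset = center shift
        recovered = t[:3, 3] + (t[:3, :3] - np.eye(3)) @ np.array([20, 20, 20])
        np.testing.assert_allclose(recovered, [3.0, 0.0, -2.0], atol=0.5)

    def test_constant_volume_rejected(self):
        flat = make_volume(np.zeros((10, 10, 10)))
        with pytest.raises(RegistrationError):
            estimate_affine(flat, ellipsoid_volume())


class TestAugment:
    def _subject(self):
        pair, masks, _ = TestPreprocessPair()._pair_with_mask()
        cube_pair, cube_masks = preprocess_pair(pair, masks,
                                                PreprocessConfig(cube_size=32))
        return cube_pair, cube_masks[0]

    def test_zero_magnitudes_identity(self):
        pair, gt = self._subject()
        cfg = AugmentConfig(rotation_max_deg=0, flip_axes=(),
                            elastic_sigma=0, elastic_alpha=0,
                            contrast_range=(1, 1), bias_field_strength=0,
                            seed=5)
        out_pair, out_gt = augment(pair, gt, cfg)
        np.testing.assert_array_equal(out_pair.baseline.data,
                                      pair.baseline.data)
        np.testing.assert_array_equal(out_gt.data, gt.data)

    def test_deterministic_in_seed(self):
        pair, gt = self._subject()
        cfg = AugmentConfig(seed=11)
        a_pair, a_gt = augment(pair, gt, cfg)
        b_pair, b_gt = augment(pair, gt, cfg)
        np.testing.assert_array_equal(a_pair.followup.data,
                                      b_pair.followup.data)
        np.testing.assert_array_equal(a_gt.data, b_gt.data)

    def test_double_flip_is_identity(self):
        pair, gt = self._subject()
        flipped = np.flip(pair.baseline.data, axis=0)
        np.testing.assert_array_equal(np.flip(flipped, axis=0),
                                      pair.baseline.data)

    def test_foreground_volume_roughly_preserved(self):
        pair, gt = self._subject()
        n0 = gt.data.sum()
        for seed in range(5):
            _, out_gt = augment(pair, gt, AugmentConfig(seed=seed))
            n1 = out_gt.data.sum()
            assert abs(int(n1) - int(n0)) / int(n0) < 0.30

    def test_spatial_transform_shared_between_images_and_mask(self):
        # with flips only, the mask must move exactly with the images
        pair, gt = self._subject()
        marker = np.zeros_like(gt.data)
        sel = pair.followup.data > pair.followup.data.mean()
        cfg = AugmentConfig(rotation_max_deg=0, elastic_alpha=0,
                            contrast_range=(1, 1), bias_field_strength=0,
                            seed=3)
        out_pair, out_gt = augment(pair, gt, cfg)
        # re-derive the flip by comparing volumes, apply to gt, compare
        for axes in ([], [0], [1], [2], [0, 1], [0, 2], [1, 2], [0, 1, 2]):
            cand = pair.followup.data
            for ax in axes:
                cand = np.flip(cand, axis=ax)
            if np.array_equal(cand, out_pair.followup.data):
                ref = gt.data
                for ax in axes:
                    ref = np.flip(ref, axis=ax)
                np.testing.assert_array_equal(ref, out_gt.data)
                return
        pytest.fail("output is not a pure flip of the input")


class TestTemplateRegistration:
    def test_template_path_resamples_onto_template_grid(self):
        moving = ellipsoid_volume(center=(21, 20, 19), noise=0.01, seed=4)
        template = ellipsoid_volume(center=(20, 20, 20), noise=0.01, seed=5)
        pair = VolumePair(moving, moving)
        mask = np.zeros(moving.shape, dtype=np.uint8)
        mask[18:23, 18:23, 18:23] = 1
        cfg = PreprocessConfig(cube_size=32, template=template)
        out_pair, out_masks = preprocess_pair(
            pair, [BinaryMask3D.from_reference(mask, moving)], cfg)
        assert out_pair.shape == (32, 32, 32)
        assert out_masks[0].data.sum() > 0  # the lesion survives the chain
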