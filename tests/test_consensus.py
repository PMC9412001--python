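"""STAPLE fusion, the consensus protocol, and unbiased ground truth."""

import numpy as np
import pytest

from lesionseg.consensus import (ExpertMaskSet,
                                 ProtocolError, build_consensus,
                                 majority_vote, partition_lesions,
                                 staple_fuse, unbiased_ground_truth)
from lesionseg.synthetic import PhantomParams, RaterModel, generate_phantom_pair, simulate_raters

from .conftest import make_mask


def blob(shape, lo, hi):
    m = np.zeros(shape, dtype=np.uint8)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return m


def expert_set(arrays, ids=None):
    return ExpertMaskSet(masks=[make_mask(a) for a in arrays],
                         rater_ids=ids or [f"r{i}"
                                           for i in range(len(arrays))])


class TestStapleFuse:
    def test_unanimous_raters_reproduce_their_mask(self):
        m = blob((16, 16, 16), (4, 4, 4), (9, 9, 9))
        post, perf = staple_fuse(expert_set([m, m, m]))
        np.testing.assert_array_equal(post > 0.5, m > 0)
        assert (perf.sensitivity > 0.99).all()

    def test_posterior_within_unit_interval(self, rng):
        arrays = [(rng.random((12, 12, 12)) < 0.2).astype(np.uint8)
                  for _ in range(3)]
        post, _ = staple_fuse(expert_set(arrays))
        assert post.min() >= 0.0 and post.max() <= 1.0

    def test_recovers_simulated_rater_performance(self, rng):
        """5 voxel-wise raters at sensitivity 0.90 / specificity 0.99 on a
        64-cube phantom truth: STAPLE recovers the sensitivities and the
        fused mask is near-perfect."""
        _, gt, _ = generate_phantom_pair(PhantomParams(seed=77))
        truth = gt.data > 0
        arrays = []
        for _ in range(5):
            noisy = np.where(truth, rng.random(truth.shape) < 0.90,
                             rng.random(truth.shape) < 0.01)
            arrays.append(noisy.astype(np.uint8))
        post, perf = staple_fuse(expert_set(arrays))
        assert np.abs(perf.sensitivity - 0.90).max() < 0.05
        assert np.abs(perf.specificity - 0.99).max() < 0.05
        fused = post > 0.5
        dice = 2 * (fused & truth).sum() / (fused.sum() + truth.sum())
        assert dice >= 0.95

    def test_two_agreeing_raters_beat_one_noisy(self, rng):
        m = blob((16, 16, 16), (3, 3, 3), (10, 10, 10))
        noise = (rng.random((16, 16, 16)) < 0.3).astype(np.uint8)
        post, _ = staple_fuse(expert_set([m, m, noise]))
        fused = post > 0.5
        agreement = (fused == (m > 0)).mean()
        assert agreement >= 0.99

    def test_single_rater_fusion_returns_own_mask(self):
        m = blob((10, 10, 10), (2, 2, 2), (6, 6, 6))
        post, _ = staple_fuse(expert_set([m]))
        np.testing.assert_array_equal(post > 0.5, m > 0)

    def test_all_empty_returns_empty_with_no_failure(self):
        z = np.zeros((8, 8, 8), dtype=np.uint8)
        post, perf = staple_fuse(expert_set([z, z]))
        assert post.sum() == 0 and perf.converged

    def test_agrees_with_sitk_staple_reference(self):
        """Cross-check against the independent STAPLE implementation in
        SimpleITK on a nontrivial disagreement pattern."""
        import SimpleITK as sitk
        rng = np.random.default_rng(4)
        truth = blob((14, 14, 14), (3, 3, 3), (10, 10, 10)) > 0
        arrays = []
        for _ in range(4):
            noisy = np.where(truth, rng.random(truth.shape) < 0.85,
                             rng.random(truth.shape) < 0.03)
            arrays.append(noisy.astype(np.uint8))
        post, _ = staple_fuse(expert_set(arrays))
        imgs = [sitk.GetImageFromArray(a) for a in arrays]
        ref = sitk.GetArrayFromImage(sitk.STAPLE(imgs, 1.0))
        ours = post > 0.5
        theirs = ref > 0.5
        agree = (ours == theirs).mean()
        assert agree > 0.99


class TestPartitionLesions:
    def test_majority_and_disputed_split(self):
        shape = (20, 20, 20)
        a = blob(shape, (2, 2, 2), (6, 6, 6))       # found by 3
        b = blob(shape, (10, 10, 10), (13, 13, 13))  # found by 1
        masks = expert_set([a | b, a, a, np.zeros(shape, dtype=np.uint8)])
        majority, disputed = partition_lesions(masks, majority_threshold=3)
        assert len(majority) == 1 and majority[0]["n_finders"] == 3
        assert len(disputed) == 1 and disputed[0]["n_finders"] == 1

    def test_empty_union_gives_empty_lists(self):
        z = np.zeros((8, 8, 8), dtype=np.uint8)
        majority, disputed = partition_lesions(expert_set([z, z, z]))
        assert majority == [] and disputed == []


class TestBuildConsensus:
    shape = (20, 20, 20)

    def test_identical_raters_consensus_is_common_mask(self):
        m = blob(self.shape, (4, 4, 4), (9, 9, 9))
        res = build_consensus(expert_set([m, m, m, m]))
        np.testing.assert_array_equal(res.mask.data, m)
        assert res.provenance[0]["status"] == "majority-auto"

    def test_disputed_rejected_absent_but_tracked(self):
        common = blob(self.shape, (2, 2, 2), (6, 6, 6))
        solo = blob(self.shape, (12, 12, 12), (15, 15, 15))
        masks = expert_set([common | solo, common, common, common])
        labels_of_solo = 2  # second component in scan order
        res = build_consensus(masks, decisions={labels_of_solo: "reject"})
        assert not (res.mask.data & solo).any()
        statuses = {p["status"] for p in res.provenance}
        assert "disputed-rejected" in statuses

    def test_disputed_accepted_single_finder_keeps_own_voxels(self):
        common = blob(self.shape, (2, 2, 2), (6, 6, 6))
        solo = blob(self.shape, (12, 12, 12), (15, 15, 15))
        masks = expert_set([common | solo, common, common, common])
        res = build_consensus(masks, decisions={2: "accept"})
        np.testing.assert_array_equal(res.mask.data & solo, solo)

    def test_missing_decision_raises_protocol_error(self):
        common = blob(self.shape, (2, 2, 2), (6, 6, 6))
        solo = blob(self.shape, (12, 12, 12), (15, 15, 15))
        masks = expert_set([common | solo, common, common, common])
        with pytest.raises(ProtocolError, match="2"):
            build_consensus(masks, decisions={})

    def test_consensus_mask_as_senior_decision_source(self):
        common = blob(self.shape, (2, 2, 2), (6, 6, 6))
        solo = blob(self.shape, (12, 12, 12), (15, 15, 15))
        masks = expert_set([common | solo, common, common, common])
        senior = make_mask(common | solo)  # senior accepted both
        res = build_consensus(masks, decisions=senior)
        assert (res.mask.data & solo).sum() == solo.sum()


class TestUnbiasedGroundTruth:
    shape = (24, 24, 24)

    def _setup(self):
        # lesion A: found by 2 remaining raters -> auto accept
        # lesion B: found by 1 remaining rater, in consensus -> accept
        # lesion C: found by 1 remaining rater, not in consensus -> reject
        a = blob(self.shape, (2, 2, 2), (7, 7, 7))
        b = blob(self.shape, (10, 10, 10), (14, 14, 14))
        c = blob(self.shape, (18, 18, 18), (22, 22, 22))
        excluded = blob(self.shape, (2, 10, 2), (5, 14, 5))
        masks = expert_set([a | b, a | c, np.zeros_like(a), excluded],
                           ids=["r0", "r1", "r2", "excl"])
        consensus = make_mask(a | b)
        return masks, consensus, a, b, c

    def test_three_decision_rules(self):
        masks, consensus, a, b, c = self._setup()
        u = unbiased_ground_truth(masks, consensus, "excl")
        assert (u.data & b).sum() == b.sum()      # single finder, in c
        assert not (u.data & c).any()             # single finder, not in c
        assert (u.data & a).any()                 # two finders

    def test_two_finder_delineation_is_majority_of_remaining(self):
        masks, consensus, a, b, c = self._setup()
        u = unbiased_ground_truth(masks, consensus, "excl")
        # only 2 of 3 remaining raters marked lesion A -> majority is their
        # intersection, which here is A itself
        np.testing.assert_array_equal((u.data & a) > 0, a > 0)

    def test_invariant_to_excluded_rater_corruption(self, rng):
        masks, consensus, *_ = self._setup()
        u1 = unbiased_ground_truth(masks, consensus, "excl")
        corrupted = [m.data.copy() for m in masks.masks]
        corrupted[3] = (rng.random(self.shape) < 0.5).astype(np.uint8)
        masks2 = expert_set(corrupted, ids=["r0", "r1", "r2", "excl"])
        u2 = unbiased_ground_truth(masks2, consensus, "excl")
        np.testing.assert_array_equal(u1.data, u2.data)

    def test_too_few_remaining_raters_rejected(self):
        z = np.zeros((8, 8, 8), dtype=np.uint8)
        masks = expert_set([z, z, z], ids=["a", "b", "c"])
        with pytest.raises(ProtocolError, match="3 remaining"):
            unbiased_ground_truth(masks, make_mask(z), "a")

    def test_majority_vote_idempotent_on_identical_masks(self):
        m = blob((10, 10, 10), (2, 2, 2), (7, 7, 7))
        np.testing.assert_array_equal(majority_vote(np.stack([m, m, m]) > 0),
                                      m > 0)

    def test_end_to_end_with_simulated_raters(self):
        _, gt, catalog = generate_phantom_pair(PhantomParams(seed=300))
        raters = [RaterModel(sensitivity=0.95, boundary_jitter_sd=0.3,
                             seed=40 + j) for j in range(4)]
        masks = ExpertMaskSet(masks=simulate_raters(gt, catalog, raters),
                              rater_ids=[f"rater{j}" for j in range(4)])
        u = unbiased_ground_truth(masks, gt, "rater3")
        assert u.shape == gt.shape
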