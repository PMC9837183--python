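"""Majority voting, Dice coefficient and the aggregate summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from bcseg.ensemble_eval import (
    dice_coefficient,
    majority_vote,
    predict_mask,
    summarize_cv,
    summarize_test,
)
from bcseg.nn import soft_dice_loss
from bcseg.phantom import SegmentationMask


def _mask(arr):
    return SegmentationMask(np.asarray(arr, dtype=np.uint8), (1.0, 1.0, 1.0))


class TestMajorityVote:
    def test_three_votes_in_two_votes_out(self):
        shape = (1, 2, 2)
        members = [np.zeros(shape, dtype=np.uint8) for _ in range(5)]
        for m in members[:3]:
            m[0, 0, 0] = 1  # 3 of 5 -> included
        for m in members[:2]:
            m[0, 1, 1] = 1  # 2 of 5 -> excluded
        out = majority_vote(members, min_votes=3)
        assert out.voxels[0, 0, 0] == 1
        assert out.voxels[0, 1, 1] == 0

    def test_unanimous_members_reproduced(self, rng):
        m = (rng.random((3, 5, 5)) < 0.4).astype(np.uint8)
        out = majority_vote([m] * 5, min_votes=3)
        assert (out.voxels == m).all()

    def test_consensus_bounded_by_union_and_intersection(self, rng):
        members = [(rng.random((3, 6, 6)) < 0.5).astype(np.uint8) for _ in range(5)]
        out = majority_vote(members, min_votes=3).voxels
        union = np.clip(np.sum(members, axis=0), 0, 1)
        inter = np.prod(members, axis=0)
        assert (out <= union).all()
        assert (out >= inter).all()

    def test_matches_brute_force_counter(self, rng):
        for _ in range(20):
            members = [(rng.random((2, 4, 4)) < 0.5).astype(np.uint8) for _ in range(5)]
            ours = majority_vote(members, min_votes=3).voxels
            ref = oracles.naive_majority_vote(members, 3)
            assert (ours == ref).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            majority_vote([np.zeros((2, 2, 2)), np.zeros((2, 2, 3))] * 2 + [np.zeros((2, 2, 2))])

    def test_non_binary_member_rejected(self):
        bad = np.full((2, 2, 2), 2)
        with pytest.raises(ValueError, match="binary"):
            majority_vote([bad] * 5)


class TestDiceCoefficient:
    def test_identical_masks_score_one(self, rng):
        m = (rng.random((3, 4, 4)) < 0.5).astype(np.uint8)
        m[0, 0, 0] = 1
        assert dice_coefficient(_mask(m), _mask(m)) == 1.0

    def test_disjoint_masks_score_zero(self):
        t = np.zeros((1, 2, 2), dtype=np.uint8)
        p = np.zeros((1, 2, 2), dtype=np.uint8)
        t[0, 0, 0] = 1
        p[0, 1, 1] = 1
        assert dice_coefficient(_mask(t), _mask(p)) == 0.0

    def test_hand_enumerated_half_overlap(self):
        """|T|=4, |P|=4, |T∩P|=2 gives 2·2/(4+4) = 0.5."""
        t = np.zeros((1, 3, 3), dtype=np.uint8)
        p = np.zeros((1, 3, 3), dtype=np.uint8)
        t[0, 0, :3] = 1
        t[0, 1, 0] = 1
        p[0, 0, :2] = 1
        p[0, 2, 1:] = 1
        assert int(t.sum()) == 4 and int(p.sum()) == 4 and int((t & p).sum()) == 2
        assert dice_coefficient(_mask(t), _mask(p)) == 0.5

    def test_both_empty_convention(self):
        z = np.zeros((2, 2, 2), dtype=np.uint8)
        assert dice_coefficient(z, z) == 1.0

    def test_one_empty_convention(self):
        z = np.zeros((2, 2, 2), dtype=np.uint8)
        o = np.ones((2, 2, 2), dtype=np.uint8)
        assert dice_coefficient(z, o) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, (2, 3, 3), elements=st.integers(0, 1)),
           hnp.arrays(np.uint8, (2, 3, 3), elements=st.integers(0, 1)))
    def test_symmetry_property(self, t, p):
        assert dice_coefficient(t, p) == dice_coefficient(p, t)

    def test_agrees_with_voxel_enumeration(self, rng):
        for _ in range(25):
            t = (rng.random((2, 4, 4)) < 0.4).astype(np.uint8)
            p = (rng.random((2, 4, 4)) < 0.4).astype(np.uint8)
            assert abs(dice_coefficient(t, p) - oracles.naive_dice(t, p)) < 1e-12

    def test_complement_of_dice_loss_on_binary_predictions(self, rng):
        """1 - soft-Dice loss at smooth→0 equals the Dice coefficient."""
        t = (rng.random((2, 4, 4)) < 0.4).astype(np.float64)
        p = (rng.random((2, 4, 4)) < 0.4).astype(np.float64)
        if t.sum() + p.sum() == 0:
            t[0, 0, 0] = 1
        per_sample = []
        for i in range(2):
            per_sample.append(1.0 - soft_dice_loss(p[i], t[i], smooth=1e-12))
        full = dice_coefficient(t.astype(np.uint8).reshape(2, 4, 4),
                                p.astype(np.uint8).reshape(2, 4, 4))
        # volume-level identity when computed on the pooled grids
        pooled = 1.0 - soft_dice_loss(p.reshape(1, -1, 4), t.reshape(1, -1, 4), smooth=1e-12)
        assert abs(pooled - full) < 1e-6


class TestSummaries:
    def test_cv_mean_and_range(self):
        s = summarize_cv([0.78, 0.81, 0.79, 0.80, 0.82])
        assert abs(s["mean"] - 0.80) < 1e-12
        assert s["range"] == (0.78, 0.82)

    def test_cv_constant_degenerate_range(self):
        s = summarize_cv([0.5] * 5)
        assert s["mean"] == 0.5
        assert s["range"] == (0.5, 0.5)

    def test_cv_mean_within_range(self, rng):
        vals = rng.random(5)
        s = summarize_cv(vals)
        assert s["range"][0] <= s["mean"] <= s["range"][1]

    def test_test_median_and_iqr(self):
        s = summarize_test([0.7, 0.8, 0.9])
        assert s["median"] == 0.8
        assert s["iqr"][0] <= s["median"] <= s["iqr"][1]

    def test_single_value_degenerate(self):
        s = summarize_test([0.6])
        assert s["median"] == 0.6
        assert s["iqr"] == (0.6, 0.6)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            summarize_cv([])
        with pytest.raises(ValueError):
            summarize_test([])


class TestPredictMask:
    class _FakeModel:
        def __init__(self, probs):
            self._p = probs

        def predict(self, stack):
            return self._p

    def _stack(self, n):
        from bcseg.preprocess import ChannelStack

        return ChannelStack(np.zeros((n, 8, 8, 3), dtype=np.float32), "multi", "t")

    def test_all_below_threshold_gives_empty_mask(self):
        model = self._FakeModel(np.full((2, 8, 8), 0.4))
        out = predict_mask(model, self._stack(2))
        assert not out.voxels.any()

    def test_tie_at_threshold_included(self):
        probs = np.zeros((1, 8, 8))
        probs[0, 3, 3] = 0.5
        out = predict_mask(self._FakeModel(probs), self._stack(1))
        assert out.voxels[0, 3, 3] == 1

    def test_voxel_count_matches_exhaustive_threshold_count(self, rng):
        probs = rng.random((3, 8, 8))
        out = predict_mask(self._FakeModel(probs), self._stack(3))
        assert int(out.voxels.sum()) == int((probs >= 0.5).sum())

    def test_slice_count_mismatch_rejected(self):
        model = self._FakeModel(np.zeros((2, 8, 8)))
        with pytest.raises(ValueError, match="slice-count"):
            predict_mask(model, self._stack(3))
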