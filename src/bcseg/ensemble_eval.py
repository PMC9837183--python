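"""Majority-vote ensembling of the cross-validation models and Dice evaluation.

A held-out case is segmented by all five cross-validation models; a voxel is
labeled tumor when at least three of the five member masks agree.  Overlap
with the reference standard T is measured by the Dice similarity coefficient

    DSC = 2|T ∩ P| / (|T| + |P|),

computed volumetrically per patient.  Cross-validation performance is
summarized as mean and (min, max) range over folds; held-out test performance
as median and interquartile range.
"""

from __future__ import annotations

import numpy as np

from .phantom import SegmentationMask
from .preprocess import ChannelStack

__all__ = [
    "predict_mask",
    "majority_vote",
    "dice_coefficient",
    "summarize_cv",
    "summarize_test",
    "ensemble_predict",
]


def predict_mask(
    model,
    stack: ChannelStack,
    prob_threshold: float = 0.5,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SegmentationMask:
    """Binarize a model's slice probabilities into a 3D mask.

    A voxel is included when its probability is >= `prob_threshold` (ties at
    the threshold are included).  `spacing` should be the source-case voxel
    spacing when known; it defaults to unit model-grid spacing.
    """
    probs = model.predict(stack)
    if probs.shape[0] != stack.n_slices:
        raise ValueError(
            f"slice-count mismatch: {probs.shape[0]} probability maps for "
            f"{stack.n_slices} input slices"
        )
    return SegmentationMask((probs >= prob_threshold).astype(np.uint8), spacing)


def _as_binary_array(mask) -> np.ndarray:
    arr = mask.voxels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    vals = np.unique(arr)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"mask is not binary, found values {vals}")
    return arr.astype(np.uint8)


def majority_vote(member_masks, min_votes: int = 3,
                  spacing: tuple[float, float, float] | None = None) -> SegmentationMask:
    """Per-voxel vote over ensemble member masks (default: >= 3 of 5).

    Accepts `SegmentationMask` objects or binary arrays; all members must
    share one shape.
    """
    members = [_as_binary_array(m) for m in member_masks]
    if not members:
        raise ValueError("no member masks given")
    shapes = {m.shape for m in members}
    if len(shapes) != 1:
        raise ValueError(f"member masks must share one shape, got {shapes}")
    if not 1 <= min_votes <= len(members):
        raise ValueError(f"min_votes={min_votes} invalid for {len(members)} members")
    if spacing is None:
        first = member_masks[0]
        spacing = first.spacing if isinstance(first, SegmentationMask) else (1.0, 1.0, 1.0)
    votes = np.sum(members, axis=0)
    return SegmentationMask((votes >= min_votes).astype(np.uint8), spacing)


def dice_coefficient(t, p) -> float:
    """Dice similarity coefficient 2|T∩P|/(|T|+|P|) between binary masks.

    Symmetric in its arguments.  By documented convention two empty masks
    score 1.0 (perfect agreement on absence) and exactly one empty mask
    scores 0.0; this keeps aggregates NaN-free.
    """
    ta, pa = _as_binary_array(t), _as_binary_array(p)
    if ta.shape != pa.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {pa.shape}")
    st, sp = int(ta.sum()), int(pa.sum())
    if st + sp == 0:
        return 1.0
    return 2.0 * int((ta & pa).sum()) / (st + sp)


def summarize_cv(per_fold_dsc, k: int = 5) -> dict:
    """Cross-validation style aggregate: mean and (min, max) over the k folds."""
    vals = np.asarray(list(per_fold_dsc), dtype=float)
    if vals.size == 0:
        raise ValueError("no fold values to summarize")
    if vals.size != k:
        raise ValueError(f"expected {k} fold values, got {vals.size}")
    return {"mean": float(vals.mean()), "range": (float(vals.min()), float(vals.max()))}


def summarize_test(per_case_dsc) -> dict:
    """Held-out test style aggregate: median and interquartile range (Q1, Q3).

    Quartiles use linear interpolation.
    """
    vals = np.asarray(list(per_case_dsc), dtype=float)
    if vals.size == 0:
        raise ValueError("no case values to summarize")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3))}


def ensemble_predict(
    models,
    stack: ChannelStack,
    min_votes: int = 3,
    prob_threshold: float = 0.5,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SegmentationMask:
    """Segment one case with the full ensemble: member masks then majority vote."""
    member_masks = [predict_mask(m, stack, prob_threshold, spacing) for m in models]
    return majority_vote(member_masks, min_votes=min_votes, spacing=spacing)
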