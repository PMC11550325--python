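"""Per-annotation scoring against ground truth.

All quantities are exact pixel set algebra on binary masks. DICE is
2|GT∩P| / (|GT|+|P|); false-positive and false-negative areas are reported
as fractions of the union |GT∪P|, so that for any non-empty union

    dice = 2(1 - fp_frac - fn_frac) / (2 - fp_frac - fn_frac).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OverlapCounts",
    "MetricRecord",
    "ChangeRecord",
    "Outcome",
    "EmptyUnionError",
    "EmptyMaskError",
    "overlap_counts",
    "dice",
    "error_fractions",
    "mask_centroid",
    "centroid_contained",
    "evaluate_annotation",
    "classify_change",
    "DICE_CHANGE_TOLERANCE",
]

#: |Δdice| below this counts as "no change in score" (effectively exact).
DICE_CHANGE_TOLERANCE = 1e-9


class EmptyUnionError(ValueError):
    """Error fractions are undefined when |GT ∪ P| = 0."""


class EmptyMaskError(ValueError):
    """Centroid of an empty mask is undefined."""


class Outcome(str, enum.Enum):
    IMPROVED = "IMPROVED"
    WORSENED = "WORSENED"
    UNCHANGED = "UNCHANGED"


@dataclass(frozen=True)
class OverlapCounts:
    tp: int  # |GT ∩ P|
    fp: int  # |P \ GT|
    fn: int  # |GT \ P|

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("overlap counts must be non-negative")

    @property
    def union(self) -> int:
        return self.tp + self.fp + self.fn

    @property
    def gt_area(self) -> int:
        return self.tp + self.fn

    @property
    def pred_area(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricRecord:
    annotator_id: str
    image_id: str
    round: "str"
    dice: float
    fp_frac: float
    fn_frac: float
    centroid_hit: bool


@dataclass(frozen=True)
class ChangeRecord:
    annotator_id: str
    image_id: str
    annotation_changed: bool
    dice_outcome: Outcome


def _check_dims(gt: np.ndarray, p: np.ndarray) -> None:
    if gt.shape != p.shape:
        raise ValueError(f"mask dimensions differ: {gt.shape} vs {p.shape}")


def overlap_counts(gt: np.ndarray, p: np.ndarray) -> OverlapCounts:
    """Exact TP/FP/FN pixel counts between two same-shape boolean masks."""
    _check_dims(gt, p)
    tp = int(np.count_nonzero(gt & p))
    fp = int(np.count_nonzero(p & ~gt))
    fn = int(np.count_nonzero(gt & ~p))
    return OverlapCounts(tp=tp, fp=fp, fn=fn)


def dice(counts: OverlapCounts) -> float:
    """DICE overlap 2·tp / (2·tp + fp + fn).

    Both masks empty -> 1.0 (perfect agreement on absence); exactly one
    empty -> 0.0.
    """
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def error_fractions(counts: OverlapCounts) -> tuple[float, float]:
    """(fp_frac, fn_frac), each normalized by the union |GT ∪ P|."""
    union = counts.union
    if union == 0:
        raise EmptyUnionError("error fractions undefined for empty union")
    return counts.fp / union, counts.fn / union


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the centers of true pixels.

    The center of pixel (r, c) is (r + 0.5, c + 0.5). May lie outside the
    true-pixel set for non-convex masks.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("centroid of an empty mask is undefined")
    return float(rows.mean() + 0.5), float(cols.mean() + 0.5)


def centroid_contained(gt: np.ndarray, p: np.ndarray) -> bool:
    """Whether the pixel containing the ground-truth centroid is labelled in p."""
    _check_dims(gt, p)
    r, c = mask_centroid(gt)
    return bool(p[int(np.floor(r)), int(np.floor(c))])


def evaluate_annotation(
    gt: np.ndarray,
    p: np.ndarray,
    *,
    annotator_id: str = "",
    image_id: str = "",
    round: str = "",
) -> MetricRecord:
    """Score one participant mask against ground truth.

    Requires non-empty ground truth (so the union is non-empty and the
    centroid defined).
    """
    counts = overlap_counts(gt, p)
    if counts.gt_area == 0:
        raise EmptyMaskError("ground truth mask is empty")
    fp_frac, fn_frac = error_fractions(counts)
    return MetricRecord(
        annotator_id=annotator_id,
        image_id=image_id,
        round=round,
        dice=dice(counts),
        fp_frac=fp_frac,
        fn_frac=fn_frac,
        centroid_hit=centroid_contained(gt, p),
    )


def classify_change(
    pre: tuple[np.ndarray, MetricRecord],
    post: tuple[np.ndarray, MetricRecord],
    *,
    tolerance: float = DICE_CHANGE_TOLERANCE,
) -> ChangeRecord:
    """Classify what an annotator did between rounds.

    "Changed" means any pixel differs between the rasterized pre and post
    masks. The dice outcome compares scores with a (near-exact) tolerance,
    so annotation_changed=False always implies UNCHANGED.
    """
    pre_mask, pre_rec = pre
    post_mask, post_rec = post
    if (pre_rec.annotator_id, pre_rec.image_id) != (post_rec.annotator_id, post_rec.image_id):
        raise ValueError(
            f"pre/post keys differ: ({pre_rec.annotator_id}, {pre_rec.image_id}) "
            f"vs ({post_rec.annotator_id}, {post_rec.image_id})"
        )
    changed = not np.array_equal(pre_mask, post_mask)
    if not changed or abs(post_rec.dice - pre_rec.dice) <= tolerance:
        outcome = Outcome.UNCHANGED
    elif post_rec.dice > pre_rec.dice:
        outcome = Outcome.IMPROVED
    else:
        outcome = Outcome.WORSENED
    return ChangeRecord(
        annotator_id=pre_rec.annotator_id,
        image_id=pre_rec.image_id,
        annotation_changed=changed,
        dice_outcome=outcome,
    )
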