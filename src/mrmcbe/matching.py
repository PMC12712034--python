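"""Bounding-box overlap and per-image TP/FP/FN classification.

A source annotation (reader or AI box) counts as a true positive when it
overlaps a ground-truth box by at least the configured threshold (default
40%).  The overlap convention is configurable because the original reader
trial never published which normalisation its 40% referred to:

* ``gt_fraction`` (default): intersection area / ground-truth box area.
  Detection-oriented — a generously large reader box that fully covers the
  fracture still scores 1.0.
* ``iou``: intersection over union, the object-detection standard.
* ``min_area_fraction``: intersection / min(area_source, area_gt).

Matching is one-to-one: among all (source, ground-truth) pairs at or above
the threshold we take the assignment with the maximum number of matched
pairs, breaking ties by maximum total overlap.  One-to-one prevents a single
sprawling box from claiming several fractures at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import Annotation, BoundingBox, StudyDataset

OverlapMode = Literal["gt_fraction", "iou", "min_area_fraction"]


@dataclass(frozen=True)
class OverlapConvention:
    """How box overlap is normalised and thresholded into a detection."""

    mode: OverlapMode = "gt_fraction"
    threshold: float = 0.40
    inclusive: bool = True  # ">= threshold" (the inclusive reading of "at least 40%")

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")

    def meets(self, overlap: float) -> bool:
        return overlap >= self.threshold if self.inclusive else overlap > self.threshold


def overlap_fraction(
    source_box: BoundingBox, gt_box: BoundingBox, convention: OverlapConvention
) -> float:
    """Normalised overlap of a source box with a ground-truth box, in [0, 1]."""
    inter = source_box.intersection_area(gt_box)
    if inter == 0.0:
        return 0.0
    if convention.mode == "gt_fraction":
        denom = gt_box.area
    elif convention.mode == "iou":
        denom = source_box.area + gt_box.area - inter
    elif convention.mode == "min_area_fraction":
        denom = min(source_box.area, gt_box.area)
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown overlap mode {convention.mode!r}")
    return inter / denom


@dataclass(frozen=True)
class MatchedPair:
    gt_index: int
    source_index: int
    overlap: float
    gt: Annotation
    source: Annotation


@dataclass(frozen=True)
class FractureMatchResult:
    """TP/FP/FN partition of all boxes on one image.

    Every ground-truth annotation appears exactly once across tp ∪ fn and
    every source annotation exactly once across tp ∪ fp.
    """

    image_id: str
    tp: tuple[MatchedPair, ...]
    fp_indices: tuple[int, ...]
    fn_indices: tuple[int, ...]
    source: tuple[Annotation, ...] = field(repr=False)
    gt: tuple[Annotation, ...] = field(repr=False)

    @property
    def fp_boxes(self) -> list[Annotation]:
        return [self.source[i] for i in self.fp_indices]

    @property
    def fn_fractures(self) -> list[Annotation]:
        return [self.gt[i] for i in self.fn_indices]

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp_indices)

    @property
    def n_fn(self) -> int:
        return len(self.fn_indices)


def match_image(
    source_annotations: Sequence[Annotation],
    gt_annotations: Sequence[Annotation],
    convention: OverlapConvention = OverlapConvention(),
    image_id: str | None = None,
) -> FractureMatchResult:
    """One-to-one optimal assignment of source boxes to ground-truth boxes.

    Pairs below the overlap threshold are ineligible.  Among eligible pairs
    the assignment maximises the number of matched pairs, then total overlap.
    Unmatched source boxes are false positives; unmatched ground-truth boxes
    are false negatives.  Fracture status is ignored here — a detection with
    the wrong acute/healing label is still a detection.
    """
    if image_id is None:
        ids = {a.image_id for a in list(source_annotations) + list(gt_annotations)}
        if len(ids) > 1:
            raise ValueError(f"annotations span multiple images: {sorted(ids)}")
        image_id = next(iter(ids)) if ids else ""

    n_s, n_g = len(source_annotations), len(gt_annotations)
    if n_s == 0 or n_g == 0:
        return FractureMatchResult(
            image_id=image_id,
            tp=(),
            fp_indices=tuple(range(n_s)),
            fn_indices=tuple(range(n_g)),
            source=tuple(source_annotations),
            gt=tuple(gt_annotations),
        )

    overlaps = np.zeros((n_s, n_g))
    for i, s in enumerate(source_annotations):
        for j, g in enumerate(gt_annotations):
            overlaps[i, j] = overlap_fraction(s.box, g.box, convention)
    eligible = np.array(
        [[convention.meets(overlaps[i, j]) for j in range(n_g)] for i in range(n_s)]
    )

    # Cardinality dominates total overlap: each matched pair carries a bonus
    # larger than any achievable overlap sum, so linear_sum_assignment's
    # max-weight solution is max-cardinality first, max-overlap second.
    bonus = float(n_s + n_g + 1)
    weights = np.where(eligible, bonus + overlaps, 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)

    pairs = []
    for i, j in zip(rows, cols):
        if eligible[i, j]:
            pairs.append(
                MatchedPair(
                    gt_index=int(j),
                    source_index=int(i),
                    overlap=float(overlaps[i, j]),
                    gt=gt_annotations[j],
                    source=source_annotations[i],
                )
            )
    pairs.sort(key=lambda p: (p.gt_index, p.source_index))
    matched_s = {p.source_index for p in pairs}
    matched_g = {p.gt_index for p in pairs}
    return FractureMatchResult(
        image_id=image_id,
        tp=tuple(pairs),
        fp_indices=tuple(i for i in range(n_s) if i not in matched_s),
        fn_indices=tuple(j for j in range(n_g) if j not in matched_g),
        source=tuple(source_annotations),
        gt=tuple(gt_annotations),
    )


def match_study(
    ds: StudyDataset,
    source_annotations: Iterable[Annotation],
    convention: OverlapConvention = OverlapConvention(),
) -> dict[str, FractureMatchResult]:
    """Match one source's annotations against ground truth on every image."""
    gt_by_image = ds.annotations_by_image(ds.ground_truth)
    src_by_image = ds.annotations_by_image(source_annotations)
    return {
        iid: match_image(src_by_image[iid], gt_by_image[iid], convention, image_id=iid)
        for iid in (im.image_id for im in ds.images)
    }


def matches_to_records(matches: dict[str, FractureMatchResult]) -> list[dict]:
    """Flatten match results to audit records (CSV-exportable)."""
    rows: list[dict] = []
    for iid in sorted(matches):
        m = matches[iid]
        for p in m.tp:
            rows.append(
                {
                    "image_id": iid,
                    "gt_index": p.gt_index,
                    "source_index": p.source_index,
                    "overlap": p.overlap,
                    "outcome": "tp",
                }
            )
        for i in m.fp_indices:
            rows.append(
                {"image_id": iid, "gt_index": "", "source_index": i, "overlap": "", "outcome": "fp"}
            )
        for j in m.fn_indices:
            rows.append(
                {"image_id": iid, "gt_index": j, "source_index": "", "overlap": "", "outcome": "fn"}
            )
    return rows
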