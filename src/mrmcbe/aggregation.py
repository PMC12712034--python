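"""Roll box-level match results up to per-fracture / per-image /
per-examination confusion counts.

The three nested scoring levels trade localization strictness for clinical
leniency:

* fracture — every ground-truth fracture must be hit by a sufficiently
  overlapping box (strictest).
* image — an image is called positive when the source drew any box on it,
  correct when the image carries any ground-truth fracture, irrespective of
  where the boxes sit.
* examination — positive when any of its images is called positive,
  irrespective of whether it is the right projection (most generous).

Per-fracture TN has no natural lesion-level unit; it is defined here as a
fracture-free image correctly left unannotated (one unit per image), which
makes per-fracture TN coincide with per-image TN for every source.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

from .matching import FractureMatchResult
from .model import Annotation, StudyDataset, StructureError

Level = Literal["fracture", "image", "examination"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at one level for one source.

    Integers per reader; fractional after averaging across readers.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    level: Level
    source_label: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict[str, float]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def _image_calls(ds: StudyDataset, annotations: Iterable[Annotation]) -> dict[str, bool]:
    by_image = ds.annotations_by_image(annotations)
    return {iid: len(anns) > 0 for iid, anns in by_image.items()}


def _gt_image_status(ds: StudyDataset) -> dict[str, bool]:
    return _image_calls(ds, ds.ground_truth)


def image_level_counts(
    ds: StudyDataset, source_annotations: Iterable[Annotation], source_label: str = ""
) -> ConfusionCounts:
    """2x2 of per-image binary calls vs ground-truth image positivity.

    Location is ignored: a box anywhere on a fracture-bearing image is an
    image-level TP even if it misses every fracture.
    """
    calls = _image_calls(ds, source_annotations)
    gt = _gt_image_status(ds)
    tp = sum(1 for iid in calls if calls[iid] and gt[iid])
    fp = sum(1 for iid in calls if calls[iid] and not gt[iid])
    fn = sum(1 for iid in calls if not calls[iid] and gt[iid])
    tn = sum(1 for iid in calls if not calls[iid] and not gt[iid])
    return ConfusionCounts(tp, fp, tn, fn, level="image", source_label=source_label)


def examination_level_counts(
    ds: StudyDataset, source_annotations: Iterable[Annotation], source_label: str = ""
) -> ConfusionCounts:
    """Examination call = OR over its images' calls; gt status likewise."""
    calls = _image_calls(ds, source_annotations)
    gt = _gt_image_status(ds)
    tp = fp = tn = fn = 0
    for ex in ds.examinations:
        if not ex.image_ids:
            raise StructureError(f"examination {ex.examination_id!r} has no images")
        call = any(calls[i] for i in ex.image_ids)
        pos = any(gt[i] for i in ex.image_ids)
        if call and pos:
            tp += 1
        elif call:
            fp += 1
        elif pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn, level="examination", source_label=source_label)


def fracture_level_counts(
    ds: StudyDataset,
    matches: Mapping[str, FractureMatchResult],
    source_label: str = "",
) -> ConfusionCounts:
    """Lesion-level counts from per-image match results.

    TP = matched ground-truth fractures, FN = unmatched ones, FP = every
    unmatched source box.  TN = fracture-free images with no source box.
    """
    tp = fp = fn = tn = 0
    for iid, m in matches.items():
        tp += m.n_tp
        fp += m.n_fp
        fn += m.n_fn
        if len(m.gt) == 0 and len(m.source) == 0:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn, level="fracture", source_label=source_label)


def average_counts(
    counts: Sequence[ConfusionCounts], source_label: str = "average"
) -> ConfusionCounts:
    """Cell-wise arithmetic mean across readers (fractional values allowed)."""
    if not counts:
        raise ValueError("average_counts requires at least one ConfusionCounts")
    levels = {c.level for c in counts}
    if len(levels) > 1:
        raise ValueError(f"cannot average counts across levels: {sorted(levels)}")
    n = len(counts)
    return ConfusionCounts(
        tp=sum(c.tp for c in counts) / n,
        fp=sum(c.fp for c in counts) / n,
        tn=sum(c.tn for c in counts) / n,
        fn=sum(c.fn for c in counts) / n,
        level=counts[0].level,
        source_label=source_label,
    )


def counts_at_level(
    ds: StudyDataset,
    annotations: Sequence[Annotation],
    matches: Mapping[str, FractureMatchResult],
    level: Level,
    source_label: str = "",
) -> ConfusionCounts:
    if level == "image":
        return image_level_counts(ds, annotations, source_label)
    if level == "examination":
        return examination_level_counts(ds, annotations, source_label)
    if level == "fracture":
        return replace(fracture_level_counts(ds, matches), source_label=source_label)
    raise ValueError(f"unknown level {level!r}")
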