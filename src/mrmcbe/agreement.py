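"""Inter-reader agreement, round-1 -> round-2 decision changes, and
acute/healing status accuracy.

Agreement is chance-corrected pairwise Cohen's kappa averaged over all
reader pairs (or over reader-AI pairs).  At the image and examination
levels every unit has a well-defined binary call for every source.  The
fracture level has no fixed unit set for false positives, so kappa there
uses ground-truth fractures plus one "any false positive on this image"
pseudo-unit per image: multiple stray boxes on one image count once.

Decision changes between the unaided and AI-assisted rounds are recorded
per unit with their direction, whether the new call agrees with ground
truth ("correct change") and whether it agrees with the AI's call on that
unit.  At the fracture level the number of reader boxes differs between
rounds, so false-positive changes are counted through the per-image FP
count delta: each added or removed false positive is one change from or to
a true negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

from .aggregation import Level
from .matching import FractureMatchResult, OverlapConvention, match_study
from .model import Annotation, ReadingRound, StudyDataset

Direction = Literal["pos_to_neg", "neg_to_pos"]


@dataclass(frozen=True)
class BinaryCallVector:
    """Per-unit binary calls for one source at one level."""

    level: Level
    source_label: str
    unit_ids: tuple[str, ...]
    calls: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.unit_ids) != len(self.calls):
            raise ValueError("unit_ids and calls must be parallel")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_positive(self) -> int:
        return sum(self.calls)

    def as_mapping(self) -> dict[str, bool]:
        return dict(zip(self.unit_ids, self.calls))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    pair_kappas: tuple[tuple[str, str, float], ...]
    n_units: int


@dataclass(frozen=True)
class ChangeRecord:
    """One round-1 -> round-2 decision change on one unit."""

    reader_id: str
    level: Level
    unit_id: str
    direction: Direction
    correct: bool  # round-2 call agrees with ground truth
    ai_aligned: bool  # round-2 call agrees with the AI's call on the unit


def _select_annotations(
    ds: StudyDataset,
    source: str,
    round: Optional[ReadingRound],
    reader_id: Optional[str],
) -> list[Annotation]:
    if source == "ground_truth":
        return ds.ground_truth
    if source == "ai":
        return ds.ai
    if source == "reader":
        if reader_id is None or round is None:
            raise ValueError("reader vectors require reader_id and round")
        return ds.reader_annotations(reader_id, round)
    raise ValueError(f"unknown source {source!r}")


def _fracture_unit_calls(
    ds: StudyDataset,
    matches: Mapping[str, FractureMatchResult],
    is_ground_truth: bool,
    include_fp_units: bool,
) -> tuple[tuple[str, ...], tuple[bool, ...]]:
    unit_ids: list[str] = []
    calls: list[bool] = []
    for im in ds.images:
        m = matches[im.image_id]
        matched_gt = {p.gt_index for p in m.tp}
        for j in range(len(m.gt)):
            unit_ids.append(f"frac:{im.image_id}:{j}")
            calls.append(True if is_ground_truth else j in matched_gt)
        if include_fp_units:
            unit_ids.append(f"fp:{im.image_id}")
            calls.append(False if is_ground_truth else m.n_fp > 0)
    return tuple(unit_ids), tuple(calls)


def call_vector(
    ds: StudyDataset,
    source: str,
    level: Level,
    round: Optional[ReadingRound] = None,
    reader_id: Optional[str] = None,
    kappa_mode: bool = False,
    convention: OverlapConvention = OverlapConvention(),
    include_fp_units: bool = True,
) -> BinaryCallVector:
    """Binary call per unit for one source at one level.

    Image/examination levels: a unit is positive when the source drew at
    least one box on it (any image of the examination).  Fracture level
    requires ``kappa_mode=True`` and uses ground-truth fractures plus one
    false-positive pseudo-unit per image.
    """
    anns = _select_annotations(ds, source, round, reader_id)
    label = source if source != "reader" else f"{reader_id}:{round}"

    if level == "fracture":
        if not kappa_mode:
            raise ValueError(
                "fracture-level call vectors are only defined in kappa_mode "
                "(ground-truth fractures + per-image FP pseudo-units)"
            )
        matches = match_study(ds, anns, convention)
        unit_ids, calls = _fracture_unit_calls(
            ds, matches, source == "ground_truth", include_fp_units
        )
        return BinaryCallVector("fracture", label, unit_ids, calls)

    by_image = ds.annotations_by_image(anns)
    if level == "image":
        unit_ids = tuple(im.image_id for im in ds.images)
        calls = tuple(len(by_image[i]) > 0 for i in unit_ids)
        return BinaryCallVector("image", label, unit_ids, calls)
    if level == "examination":
        unit_ids = tuple(ex.examination_id for ex in ds.examinations)
        calls = tuple(
            any(len(by_image[i]) > 0 for i in ex.image_ids) for ex in ds.examinations
        )
        return BinaryCallVector("examination", label, unit_ids, calls)
    raise ValueError(f"unknown level {level!r}")


def cohens_kappa(a: BinaryCallVector, b: BinaryCallVector) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e comes from the product of marginals.  Two raters
    that are constant and identical agree perfectly by construction and get
    kappa = 1; any other degenerate case (p_e = 1 otherwise unreachable)
    would be NaN.
    """
    if a.unit_ids != b.unit_ids:
        raise ValueError("call vectors are over different unit sets")
    n = a.n_units
    if n == 0:
        return math.nan
    n11 = sum(1 for x, y in zip(a.calls, b.calls) if x and y)
    n00 = sum(1 for x, y in zip(a.calls, b.calls) if not x and not y)
    pa_pos = a.n_positive / n
    pb_pos = b.n_positive / n
    p_o = (n11 + n00) / n
    p_e = pa_pos * pb_pos + (1 - pa_pos) * (1 - pb_pos)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else math.nan
    return (p_o - p_e) / (1 - p_e)


def mean_pairwise_kappa(vectors: Sequence[BinaryCallVector]) -> KappaResult:
    """Arithmetic mean of Cohen's kappa over all C(R, 2) reader pairs."""
    if len(vectors) < 2:
        raise ValueError("mean pairwise kappa requires at least 2 raters")
    pairs = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            pairs.append(
                (
                    vectors[i].source_label,
                    vectors[j].source_label,
                    cohens_kappa(vectors[i], vectors[j]),
                )
            )
    kappas = [k for _, _, k in pairs]
    return KappaResult(
        kappa=sum(kappas) / len(kappas),
        pair_kappas=tuple(pairs),
        n_units=vectors[0].n_units,
    )


def readers_vs_ai_kappa(
    reader_vectors: Sequence[BinaryCallVector], ai_vector: BinaryCallVector
) -> KappaResult:
    """Mean of each reader's kappa with the AI."""
    if not reader_vectors:
        raise ValueError("need at least one reader vector")
    pairs = tuple(
        (v.source_label, ai_vector.source_label, cohens_kappa(v, ai_vector))
        for v in reader_vectors
    )
    kappas = [k for _, _, k in pairs]
    return KappaResult(sum(kappas) / len(kappas), pairs, ai_vector.n_units)


# -- intra-reader change analysis ---------------------------------------------

_EMPTY = lambda: {"n": 0, "correct": 0, "wrong": 0}  # noqa: E731


@dataclass
class ChangeSummary:
    """Nested change counts for one reader at one level.

    ``total_units`` is the rate denominator: number of examinations or
    images, or (fracture level) ground-truth fractures plus distinct
    false-positive events across both rounds.
    """

    reader_id: str
    level: Level
    total_units: float
    overall: dict
    pos_to_neg: dict
    neg_to_pos: dict
    agree_ai: dict
    disagree_ai: dict


def _tally(records: Sequence[ChangeRecord]) -> dict:
    d = _EMPTY()
    d["n"] = len(records)
    d["correct"] = sum(1 for r in records if r.correct)
    d["wrong"] = d["n"] - d["correct"]
    return d


def _nested(records: Sequence[ChangeRecord]) -> dict:
    d = _tally(records)
    d["pos_to_neg"] = _tally([r for r in records if r.direction == "pos_to_neg"])
    d["neg_to_pos"] = _tally([r for r in records if r.direction == "neg_to_pos"])
    return d


def _summarize(
    reader_id: str, level: Level, total_units: float, records: Sequence[ChangeRecord]
) -> ChangeSummary:
    return ChangeSummary(
        reader_id=reader_id,
        level=level,
        total_units=total_units,
        overall=_tally(records),
        pos_to_neg=_tally([r for r in records if r.direction == "pos_to_neg"]),
        neg_to_pos=_tally([r for r in records if r.direction == "neg_to_pos"]),
        agree_ai=_nested([r for r in records if r.ai_aligned]),
        disagree_ai=_nested([r for r in records if not r.ai_aligned]),
    )


def intra_reader_changes(
    ds: StudyDataset,
    reader_id: str,
    level: Level,
    convention: OverlapConvention = OverlapConvention(),
    fracture_denominator: Literal["gt_plus_fp_events", "gt_only"] = "gt_plus_fp_events",
) -> tuple[list[ChangeRecord], ChangeSummary]:
    """All round-1 -> round-2 decision changes for one reader at one level.

    Image/examination: per-unit binary-call comparison.  Fracture: detection
    flips per ground-truth fracture, plus one record per unit change of the
    per-image false-positive count (removal lands on a true negative and is
    a correct change; addition is a wrong one).  AI alignment of FP-delta
    records uses the AI's image-level call.
    """
    r1 = ds.reader_annotations(reader_id, "r1")
    r2 = ds.reader_annotations(reader_id, "r2")
    if not r1 or not r2:
        missing = [rd for rd, anns in (("r1", r1), ("r2", r2)) if not anns]
        raise ValueError(f"reader {reader_id!r} has no annotations in round(s) {missing}")

    records: list[ChangeRecord] = []
    if level in ("image", "examination"):
        v1 = call_vector(ds, "reader", level, "r1", reader_id)
        v2 = call_vector(ds, "reader", level, "r2", reader_id)
        gt = call_vector(ds, "ground_truth", level)
        ai = call_vector(ds, "ai", level)
        for uid, c1, c2, g, a in zip(v1.unit_ids, v1.calls, v2.calls, gt.calls, ai.calls):
            if c1 == c2:
                continue
            records.append(
                ChangeRecord(
                    reader_id=reader_id,
                    level=level,
                    unit_id=uid,
                    direction="pos_to_neg" if c1 else "neg_to_pos",
                    correct=(c2 == g),
                    ai_aligned=(c2 == a),
                )
            )
        return records, _summarize(reader_id, level, v1.n_units, records)

    if level != "fracture":
        raise ValueError(f"unknown level {level!r}")

    m1 = match_study(ds, r1, convention)
    m2 = match_study(ds, r2, convention)
    mai = match_study(ds, ds.ai, convention)
    ai_image = call_vector(ds, "ai", "image").as_mapping()

    n_fp_events = 0
    for im in ds.images:
        iid = im.image_id
        det1 = {p.gt_index for p in m1[iid].tp}
        det2 = {p.gt_index for p in m2[iid].tp}
        det_ai = {p.gt_index for p in mai[iid].tp}
        for j in range(len(m1[iid].gt)):
            c1, c2 = j in det1, j in det2
            if c1 != c2:
                records.append(
                    ChangeRecord(
                        reader_id=reader_id,
                        level="fracture",
                        unit_id=f"frac:{iid}:{j}",
                        direction="pos_to_neg" if c1 else "neg_to_pos",
                        correct=c2,  # the unit is a real fracture
                        ai_aligned=(c2 == (j in det_ai)),
                    )
                )
        fp1, fp2 = m1[iid].n_fp, m2[iid].n_fp
        n_fp_events += max(fp1, fp2)
        delta = fp2 - fp1
        if delta != 0:
            direction: Direction = "neg_to_pos" if delta > 0 else "pos_to_neg"
            for _ in range(abs(delta)):
                records.append(
                    ChangeRecord(
                        reader_id=reader_id,
                        level="fracture",
                        unit_id=f"fp:{iid}",
                        direction=direction,
                        # removing an FP lands on a true negative
                        correct=(delta < 0),
                        ai_aligned=(ai_image[iid] if delta > 0 else not ai_image[iid]),
                    )
                )
    n_gt = len(ds.ground_truth)
    total = float(n_gt + n_fp_events) if fracture_denominator == "gt_plus_fp_events" else float(n_gt)
    return records, _summarize(reader_id, "fracture", total, records)


def _pct(n: float, total: float) -> Optional[float]:
    return None if total == 0 else 100.0 * n / total


def change_table(summaries: Sequence[ChangeSummary]):
    """Average change counts across readers, in the nested table layout
    (overall, direction subgroups, AI agreement/disagreement subgroups,
    each split into correct/wrong).  Percentages use mean numerator over
    mean denominator."""
    import pandas as pd

    if not summaries:
        raise ValueError("no change summaries to tabulate")
    levels = {s.level for s in summaries}
    if len(levels) > 1:
        raise ValueError(f"summaries span multiple levels: {sorted(levels)}")
    R = len(summaries)

    def mean(path) -> float:
        total = 0.0
        for s in summaries:
            node = s
            for key in path[:-1]:
                node = getattr(node, key) if isinstance(node, ChangeSummary) else node[key]
            total += (getattr(node, path[-1]) if isinstance(node, ChangeSummary) else node[path[-1]])
        return total / R

    total_units = sum(s.total_units for s in summaries) / R
    n_overall = mean(["overall", "n"])
    rows = [("overall", n_overall, total_units)]
    rows.append(("overall/correct", mean(["overall", "correct"]), n_overall))
    rows.append(("overall/wrong", mean(["overall", "wrong"]), n_overall))
    for grp in ("pos_to_neg", "neg_to_pos"):
        n_g = mean([grp, "n"])
        rows.append((grp, n_g, n_overall))
        rows.append((f"{grp}/correct", mean([grp, "correct"]), n_g))
        rows.append((f"{grp}/wrong", mean([grp, "wrong"]), n_g))
    for ali, name in (("disagree_ai", "disagree_ai"), ("agree_ai", "agree_ai")):
        n_a = mean([ali, "n"])
        rows.append((name, n_a, n_overall))
        rows.append((f"{name}/correct", mean([ali, "correct"]), n_a))
        rows.append((f"{name}/wrong", mean([ali, "wrong"]), n_a))
        for grp in ("pos_to_neg", "neg_to_pos"):
            n_g = mean([ali, grp, "n"])
            rows.append((f"{name}/{grp}", n_g, n_a))
            rows.append((f"{name}/{grp}/correct", mean([ali, grp, "correct"]), n_g))
            rows.append((f"{name}/{grp}/wrong", mean([ali, grp, "wrong"]), n_g))
    return pd.DataFrame(
        [(name, n, tot, _pct(n, tot)) for name, n, tot in rows],
        columns=["row", "n", "total", "percent"],
    )


# -- acute vs healing status accuracy -----------------------------------------


def status_accuracy(
    ds: StudyDataset,
    round: ReadingRound,
    reader_id: Optional[str] = None,
    source: str = "reader",
    convention: OverlapConvention = OverlapConvention(),
) -> tuple[Optional[float], int, int]:
    """Proportion of detection TPs whose acute/healing label matches ground
    truth, pooled over all readers unless ``reader_id`` is given.

    Returns ``(accuracy or None, n_correct, n_tp)``; accuracy is None when
    there are no TPs.  The AI carries no status labels, so asking for it is
    an error.
    """
    if source == "ai":
        raise ValueError("the AI reader carries no acute/healing status labels")
    if source != "reader":
        raise ValueError(f"status accuracy is defined for readers, not {source!r}")
    readers = [reader_id] if reader_id is not None else ds.reader_ids
    n_tp = n_correct = 0
    for rid in readers:
        matches = match_study(ds, ds.reader_annotations(rid, round), convention)
        for m in matches.values():
            for p in m.tp:
                n_tp += 1
                if p.source.status == p.gt.status:
                    n_correct += 1
    return (n_correct / n_tp if n_tp else None), n_correct, n_tp
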