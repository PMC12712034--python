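"""Failure analysis: units where a reader majority contradicted the AI.

Round-1 reader calls are compared with the standalone AI at the fracture
level.  For every ground-truth fracture the comparison is detection vs
miss; for false positives, which need not share a location, the comparison
is the presence of any stray box on the image.  A case is emitted when at
least ``majority_threshold`` readers (default 5 of 7) called the unit
differently from the AI, and is categorised by who was right under ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .matching import OverlapConvention, match_study
from .model import ReadingRound, StudyDataset

FailureCategory = Literal[
    "ai_correct_reader_overcall_fp",
    "ai_correct_reader_undercall_fn",
    "reader_correct_ai_overcall_fp",
    "reader_correct_ai_undercall_fn",
]

_CATEGORY_ORDER: tuple[FailureCategory, ...] = (
    "ai_correct_reader_overcall_fp",
    "ai_correct_reader_undercall_fn",
    "reader_correct_ai_overcall_fp",
    "reader_correct_ai_undercall_fn",
)


@dataclass(frozen=True)
class FailureCase:
    unit_id: str
    n_readers_contradicting_ai: int
    category: FailureCategory


def find_majority_disagreements(
    ds: StudyDataset,
    convention: OverlapConvention = OverlapConvention(),
    majority_threshold: int = 5,
    round: ReadingRound = "r1",
):
    """Fracture/FP-site units where >= ``majority_threshold`` readers
    contradicted the AI, with a category count table.

    Returns ``(cases, table)`` where ``table`` is a DataFrame with one row
    per category and one column per contradicting-reader count plus a
    total.
    """
    import pandas as pd

    reader_ids = ds.reader_ids
    n_readers = len(reader_ids)
    if n_readers < majority_threshold:
        raise ValueError(
            f"majority threshold {majority_threshold} exceeds the "
            f"{n_readers} available readers"
        )

    ai_matches = match_study(ds, ds.ai, convention)
    reader_matches = {
        rid: match_study(ds, ds.reader_annotations(rid, round), convention)
        for rid in reader_ids
    }

    cases: list[FailureCase] = []
    for im in ds.images:
        iid = im.image_id
        ai_m = ai_matches[iid]
        ai_det = {p.gt_index for p in ai_m.tp}

        for j in range(len(ai_m.gt)):
            n_detected = sum(
                1
                for rid in reader_ids
                if j in {p.gt_index for p in reader_matches[rid][iid].tp}
            )
            if j in ai_det:
                n_contra = n_readers - n_detected  # readers who missed it
                category: FailureCategory = "ai_correct_reader_undercall_fn"
            else:
                n_contra = n_detected  # readers who found what AI missed
                category = "reader_correct_ai_undercall_fn"
            if n_contra >= majority_threshold:
                cases.append(FailureCase(f"frac:{iid}:{j}", n_contra, category))

        # FP sites: presence of any stray box on the image, location-free.
        ai_fp = ai_m.n_fp > 0
        n_reader_fp = sum(1 for rid in reader_ids if reader_matches[rid][iid].n_fp > 0)
        if ai_fp:
            n_contra = n_readers - n_reader_fp  # readers correctly clean
            category = "reader_correct_ai_overcall_fp"
        else:
            n_contra = n_reader_fp  # readers overcalling where AI is clean
            category = "ai_correct_reader_overcall_fp"
        if n_contra >= majority_threshold:
            cases.append(FailureCase(f"fp:{iid}", n_contra, category))

    count_cols = list(range(majority_threshold, n_readers + 1))
    table = pd.DataFrame(
        0, index=list(_CATEGORY_ORDER), columns=[str(c) for c in count_cols] + ["total"]
    )
    for case in cases:
        table.loc[case.category, str(case.n_readers_contradicting_ai)] += 1
        table.loc[case.category, "total"] += 1
    return cases, table
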