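"""Domain types and I/O for two-round multireader fracture-detection studies.

The study structure mirrors a retrospective reader trial: a consensus ground
truth annotated with bounding boxes on radiographic images, seven (or any
number of) radiologists reading every image in two rounds (round 1 unaided,
round 2 with the AI output visible), and one standalone AI reader.  Images
are grouped into examinations, examinations belong to patients.

Coordinates are continuous pixels, origin top-left, boxes half-open
``[x_min, x_max) x [y_min, y_max)`` so that adjacent boxes sharing an edge do
not intersect.  Identifiers are opaque strings.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

Source = Literal["ground_truth", "reader", "ai"]
ReadingRound = Literal["r1", "r2"]
FractureStatus = Literal["acute", "healing"]
Certainty = Literal["certain", "doubtful"]
Sex = Literal["male", "female"]
BodyRegion = Literal["upper_limb", "lower_limb", "pelvis"]


class SchemaError(ValueError):
    """A record violates the study file schema or a type invariant."""


class StructureError(Exception):
    """Cross-record structural inconsistency (dangling ids, bad partition)."""


class BoundingBox(BaseModel):
    """Axis-aligned pixel rectangle; the unit of fracture localization."""

    model_config = ConfigDict(frozen=True)

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @model_validator(mode="after")
    def _check_extent(self) -> "BoundingBox":
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}): require x_min < x_max and "
                "y_min < y_max"
            )
        return self

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def intersection_area(self, other: "BoundingBox") -> float:
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if w <= 0.0 or h <= 0.0:
            return 0.0
        return w * h


class Annotation(BaseModel):
    """One bounding box drawn by one source on one image.

    ``reader_id`` and ``round`` are present exactly for reader annotations.
    Ground truth and readers always carry an acute/healing ``status``; the AI
    never does (it cannot grade healing).  The optional ``certainty`` flag is
    carried through untouched — every positive finding is treated as positive
    regardless of certainty.
    """

    model_config = ConfigDict(frozen=True)

    image_id: str
    source: Source
    reader_id: Optional[str] = None
    round: Optional[ReadingRound] = None
    box: BoundingBox
    status: Optional[FractureStatus] = None
    certainty: Optional[Certainty] = None

    @model_validator(mode="after")
    def _check_source_fields(self) -> "Annotation":
        if (self.reader_id is not None) != (self.source == "reader"):
            raise ValueError(
                f"annotation on image {self.image_id!r}: reader_id must be "
                "present iff source='reader'"
            )
        if (self.round is not None) != (self.source == "reader"):
            raise ValueError(
                f"annotation on image {self.image_id!r}: round must be "
                "present iff source='reader'"
            )
        if self.source in ("ground_truth", "reader"):
            if self.status is None:
                raise ValueError(
                    f"annotation on image {self.image_id!r}: {self.source} "
                    "annotations require an acute/healing status"
                )
        elif self.status is not None:
            raise ValueError(
                f"annotation on image {self.image_id!r}: AI annotations "
                "carry no acute/healing status"
            )
        return self


class PatientRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    sex: Optional[Sex] = None
    age: Optional[float] = None


class ImageRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    image_id: str
    examination_id: str
    body_region: BodyRegion
    width: float
    height: float


class ExaminationRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    examination_id: str
    patient_id: str
    image_ids: tuple[str, ...]


class StudyDataset(BaseModel):
    """A complete validated study: structure plus every annotation set."""

    model_config = ConfigDict(frozen=True)

    patients: tuple[PatientRecord, ...]
    examinations: tuple[ExaminationRecord, ...]
    images: tuple[ImageRecord, ...]
    annotations: tuple[Annotation, ...]

    # model_post_init rather than a validator so StructureError propagates
    # unwrapped (cross-record checks are not per-field schema errors)
    def model_post_init(self, __context) -> None:
        image_ids = [im.image_id for im in self.images]
        if len(set(image_ids)) != len(image_ids):
            raise StructureError("duplicate image_id in images")
        exam_ids = [ex.examination_id for ex in self.examinations]
        if len(set(exam_ids)) != len(exam_ids):
            raise StructureError("duplicate examination_id in examinations")
        patient_ids = {p.patient_id for p in self.patients}

        seen_images: set[str] = set()
        for ex in self.examinations:
            if ex.patient_id not in patient_ids:
                raise StructureError(
                    f"examination {ex.examination_id!r} references unknown "
                    f"patient {ex.patient_id!r}"
                )
            for iid in ex.image_ids:
                if iid in seen_images:
                    raise StructureError(
                        f"image {iid!r} appears in more than one examination"
                    )
                seen_images.add(iid)
        if seen_images != set(image_ids):
            missing = set(image_ids) - seen_images
            extra = seen_images - set(image_ids)
            raise StructureError(
                "examination image lists must partition the image set "
                f"(unassigned: {sorted(missing)[:5]}, dangling: {sorted(extra)[:5]})"
            )
        for im in self.images:
            if im.examination_id not in set(exam_ids):
                raise StructureError(
                    f"image {im.image_id!r} references unknown examination "
                    f"{im.examination_id!r}"
                )
        known = set(image_ids)
        for i, ann in enumerate(self.annotations):
            if ann.image_id not in known:
                raise StructureError(
                    f"annotation #{i} references unknown image {ann.image_id!r}"
                )

    # -- convenience accessors ------------------------------------------------

    @property
    def ground_truth(self) -> list[Annotation]:
        return [a for a in self.annotations if a.source == "ground_truth"]

    @property
    def ai(self) -> list[Annotation]:
        return [a for a in self.annotations if a.source == "ai"]

    def reader_annotations(self, reader_id: str, round: ReadingRound) -> list[Annotation]:
        return [
            a
            for a in self.annotations
            if a.source == "reader" and a.reader_id == reader_id and a.round == round
        ]

    @property
    def reader_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.annotations:
            if a.source == "reader" and a.reader_id is not None:
                seen.setdefault(a.reader_id)
        return list(seen)

    def annotations_by_image(self, annotations: Iterable[Annotation]) -> dict[str, list[Annotation]]:
        """Group a list of annotations by image, including empty images."""
        out: dict[str, list[Annotation]] = {im.image_id: [] for im in self.images}
        for a in annotations:
            out[a.image_id].append(a)
        return out

    def images_of_examination(self, examination_id: str) -> list[str]:
        for ex in self.examinations:
            if ex.examination_id == examination_id:
                return list(ex.image_ids)
        raise StructureError(f"unknown examination {examination_id!r}")


# -- summarization ------------------------------------------------------------


def summarize_dataset(ds: StudyDataset):
    """Dataset distribution table: patients by sex, examinations and images
    split by fracture presence (ground truth only), fractures by status.

    Returns a pandas DataFrame with columns ``group, a, b, total`` where
    (a, b) are (male, female) for patients, (fracture, no fracture) for
    examinations/images, and (acute, healing) for fractures.
    """
    import pandas as pd

    gt_by_image = ds.annotations_by_image(ds.ground_truth)
    pos_images = {iid for iid, anns in gt_by_image.items() if anns}
    pos_exams = {
        ex.examination_id
        for ex in ds.examinations
        if any(iid in pos_images for iid in ex.image_ids)
    }
    n_male = sum(1 for p in ds.patients if p.sex == "male")
    n_female = sum(1 for p in ds.patients if p.sex == "female")
    gt = ds.ground_truth
    n_acute = sum(1 for a in gt if a.status == "acute")
    rows = [
        ("patients (male/female)", n_male, n_female, len(ds.patients)),
        (
            "examinations (fracture/none)",
            len(pos_exams),
            len(ds.examinations) - len(pos_exams),
            len(ds.examinations),
        ),
        (
            "images (fracture/none)",
            len(pos_images),
            len(ds.images) - len(pos_images),
            len(ds.images),
        ),
        ("fractures (acute/healing)", n_acute, len(gt) - n_acute, len(gt)),
    ]
    return pd.DataFrame(rows, columns=["group", "a", "b", "total"])


# -- readers / writers ---------------------------------------------------------

_ANN_FIELDS = [
    "image_id",
    "source",
    "reader_id",
    "round",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "status",
    "certainty",
]


def _ann_to_flat(a: Annotation) -> dict:
    return {
        "image_id": a.image_id,
        "source": a.source,
        "reader_id": a.reader_id or "",
        "round": a.round or "",
        "x_min": repr(a.box.x_min),
        "y_min": repr(a.box.y_min),
        "x_max": repr(a.box.x_max),
        "y_max": repr(a.box.y_max),
        "status": a.status or "",
        "certainty": a.certainty or "",
    }


def _ann_from_flat(row: dict, where: str) -> Annotation:
    try:
        return Annotation(
            image_id=row["image_id"],
            source=row["source"],
            reader_id=row.get("reader_id") or None,
            round=row.get("round") or None,
            box=BoundingBox(
                x_min=float(row["x_min"]),
                y_min=float(row["y_min"]),
                x_max=float(row["x_max"]),
                y_max=float(row["y_max"]),
            ),
            status=row.get("status") or None,
            certainty=row.get("certainty") or None,
        )
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def _dataset_from_parts(patients, examinations, images, annotations, where: str) -> StudyDataset:
    try:
        return StudyDataset(
            patients=patients,
            examinations=examinations,
            images=images,
            annotations=annotations,
        )
    except StructureError:
        raise
    except ValueError as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def read_study(path: str | Path, format: Literal["json", "csv_bundle"] = "json") -> StudyDataset:
    """Read and validate a study from a JSON file or a CSV bundle directory.

    Errors name the offending file and record; dangling identifiers raise
    :class:`StructureError`.
    """
    path = Path(path)
    if format == "json":
        return _read_json(path)
    if format == "csv_bundle":
        return _read_csv_bundle(path)
    raise ValueError(f"unknown format {format!r}")


def write_study(ds: StudyDataset, path: str | Path, format: Literal["json", "csv_bundle"] = "json") -> None:
    path = Path(path)
    if format == "json":
        _write_json(ds, path)
    elif format == "csv_bundle":
        _write_csv_bundle(ds, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_json(path: Path) -> StudyDataset:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    for key in ("patients", "examinations", "images", "annotations"):
        if key not in raw:
            raise SchemaError(f"{path}: missing top-level key {key!r}")
    anns = []
    for i, rec in enumerate(raw["annotations"]):
        try:
            anns.append(Annotation.model_validate(rec))
        except ValueError as exc:
            raise SchemaError(f"{path}: annotations[{i}]: {exc}") from exc

    def _load(model, key):
        out = []
        for i, rec in enumerate(raw[key]):
            try:
                out.append(model.model_validate(rec))
            except ValueError as exc:
                raise SchemaError(f"{path}: {key}[{i}]: {exc}") from exc
        return out

    return _dataset_from_parts(
        _load(PatientRecord, "patients"),
        _load(ExaminationRecord, "examinations"),
        _load(ImageRecord, "images"),
        anns,
        str(path),
    )


def _write_json(ds: StudyDataset, path: Path) -> None:
    payload = {
        "patients": [p.model_dump(exclude_none=True) for p in ds.patients],
        "examinations": [
            {**e.model_dump(), "image_ids": list(e.image_ids)} for e in ds.examinations
        ],
        "images": [im.model_dump() for im in ds.images],
        "annotations": [a.model_dump(exclude_none=True) for a in ds.annotations],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def _read_csv_bundle(dirpath: Path) -> StudyDataset:
    def rows(name):
        p = dirpath / name
        if not p.exists():
            raise SchemaError(f"{p}: file missing from CSV bundle")
        with open(p, newline="", encoding="utf-8") as fh:
            yield from ((i, r) for i, r in enumerate(csv.DictReader(fh)))

    images = []
    for i, r in rows("images.csv"):
        try:
            images.append(
                ImageRecord(
                    image_id=r["image_id"],
                    examination_id=r["examination_id"],
                    body_region=r["body_region"],
                    width=float(r["width"]),
                    height=float(r["height"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{dirpath / 'images.csv'}: row {i}: {exc}") from exc

    examinations = []
    patients: dict[str, PatientRecord] = {}
    for i, r in rows("examinations.csv"):
        try:
            examinations.append(
                ExaminationRecord(
                    examination_id=r["examination_id"],
                    patient_id=r["patient_id"],
                    image_ids=tuple(x for x in r["image_ids"].split(";") if x),
                )
            )
            pid = r["patient_id"]
            if pid not in patients:
                patients[pid] = PatientRecord(
                    patient_id=pid,
                    sex=r.get("patient_sex") or None,
                    age=float(r["patient_age"]) if r.get("patient_age") else None,
                )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{dirpath / 'examinations.csv'}: row {i}: {exc}") from exc

    annotations = [
        _ann_from_flat(r, f"{dirpath / 'annotations.csv'}: row {i}")
        for i, r in rows("annotations.csv")
    ]
    return _dataset_from_parts(
        list(patients.values()), examinations, images, annotations, str(dirpath)
    )


def _write_csv_bundle(ds: StudyDataset, dirpath: Path) -> None:
    dirpath.mkdir(parents=True, exist_ok=True)
    by_patient = {p.patient_id: p for p in ds.patients}

    with open(dirpath / "images.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["image_id", "examination_id", "body_region", "width", "height"]
        )
        w.writeheader()
        for im in ds.images:
            w.writerow(
                {
                    "image_id": im.image_id,
                    "examination_id": im.examination_id,
                    "body_region": im.body_region,
                    "width": repr(im.width),
                    "height": repr(im.height),
                }
            )

    with open(dirpath / "examinations.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=["examination_id", "patient_id", "image_ids", "patient_sex", "patient_age"],
        )
        w.writeheader()
        for ex in ds.examinations:
            p = by_patient[ex.patient_id]
            w.writerow(
                {
                    "examination_id": ex.examination_id,
                    "patient_id": ex.patient_id,
                    "image_ids": ";".join(ex.image_ids),
                    "patient_sex": p.sex or "",
                    "patient_age": repr(p.age) if p.age is not None else "",
                }
            )

    with open(dirpath / "annotations.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_ANN_FIELDS)
        w.writeheader()
        for a in ds.annotations:
            w.writerow(_ann_to_flat(a))


def study_json_schema() -> dict:
    """JSON schema for the study file format (exported from the models)."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "TwoRoundReaderStudy",
        "type": "object",
        "required": ["patients", "examinations", "images", "annotations"],
        "properties": {
            "patients": {"type": "array", "items": PatientRecord.model_json_schema()},
            "examinations": {"type": "array", "items": ExaminationRecord.model_json_schema()},
            "images": {"type": "array", "items": ImageRecord.model_json_schema()},
            "annotations": {"type": "array", "items": Annotation.model_json_schema()},
        },
    }
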