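"""Shared fixtures: handcrafted miniature studies and generated ones."""

from __future__ import annotations

import pytest

from mrmcbe import (
    Annotation,
    BoundingBox,
    ExaminationRecord,
    ImageRecord,
    PatientRecord,
    SimulationConfig,
    StudyDataset,
    generate_study,
)
from mrmcbe.simulate import ReaderProfile


def bb(x0: float, y0: float, x1: float, y1: float) -> BoundingBox:
    return BoundingBox(x_min=x0, y_min=y0, x_max=x1, y_max=y1)


def gt_ann(image_id: str, box: BoundingBox, status: str = "healing") -> Annotation:
    return Annotation(image_id=image_id, source="ground_truth", box=box, status=status)


def reader_ann(
    image_id: str, box: BoundingBox, reader_id: str, round: str, status: str = "healing"
) -> Annotation:
    return Annotation(
        image_id=image_id, source="reader", reader_id=reader_id, round=round,
        box=box, status=status,
    )


def ai_ann(image_id: str, box: BoundingBox, certainty: str | None = None) -> Annotation:
    return Annotation(image_id=image_id, source="ai", box=box, certainty=certainty)


def build_study(
    exam_images: dict[str, list[str]],
    annotations: list[Annotation],
    width: float = 1000.0,
    height: float = 1000.0,
) -> StudyDataset:
    """Assemble a valid study from an exam -> image-ids mapping plus
    annotations; one patient per examination."""
    patients = [
        PatientRecord(patient_id=f"pat-{eid}") for eid in exam_images
    ]
    exams = [
        ExaminationRecord(examination_id=eid, patient_id=f"pat-{eid}", image_ids=tuple(iids))
        for eid, iids in exam_images.items()
    ]
    images = [
        ImageRecord(
            image_id=iid, examination_id=eid, body_region="lower_limb",
            width=width, height=height,
        )
        for eid, iids in exam_images.items()
        for iid in iids
    ]
    return StudyDataset(
        patients=tuple(patients),
        examinations=tuple(exams),
        images=tuple(images),
        annotations=tuple(annotations),
    )


SMALL_CONFIG = SimulationConfig(n_examinations=20, n_patients=9)


@pytest.fixture(scope="session")
def small_study() -> StudyDataset:
    """A compact generated study (20 examinations, 7 readers, AI)."""
    return generate_study(SMALL_CONFIG, seed=1)


@pytest.fixture(scope="session")
def three_reader_study() -> StudyDataset:
    """Even smaller: 12 examinations, 3 readers."""
    cfg = SimulationConfig(n_examinations=12, n_patients=6)
    readers = [ReaderProfile(reader_id=f"R{i}") for i in range(1, 4)]
    return generate_study(cfg, readers, seed=2)


@pytest.fixture(scope="session")
def default_study() -> StudyDataset:
    """Full default-size study (107 examinations, 7 readers), seed 1."""
    return generate_study(seed=1)
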