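"""Synthetic two-round reader-study generator.

Emulates the structure of a paediatric bone-fragility fracture reader
trial: ~48 patients contributing ~107 examinations of ~336 radiographs,
with ~206 consensus ground-truth fractures (mostly healing), seven
radiologists reading every image twice (round 1 unaided, round 2 with the
AI output visible) and one standalone AI reader.

The generator is label-exact by construction: ground-truth boxes never
overlap each other, detected boxes are jittered copies of the ground-truth
box, and false-positive boxes are rejection-sampled to be disjoint from
every ground-truth box, so the simulated TP/FP/FN identity of every box is
known and usable as an oracle for the matching pipeline.  Round-2 behaviour
operates on per-unit binary calls (each ground-truth fracture, plus one
false-positive-presence unit per image): when a reader flips to a positive
AI call they inherit the AI's box geometry.

Randomness is a single seeded stream per (study seed, source, round),
keyed by reader id, so per-reader output is reproducible under reader
re-ordering.
"""

from __future__ import annotations

import zlib
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .matching import OverlapConvention
from .model import (
    Annotation,
    BoundingBox,
    ExaminationRecord,
    ImageRecord,
    PatientRecord,
    StudyDataset,
)

_PLACEMENT_RETRIES = 500


class SimulationConfig(BaseModel):
    """Study-structure parameters; defaults reproduce the reference trial's
    dataset distribution in expectation (48 patients, 107 examinations,
    ~336 images, ~206 fractures, 40/206 acute)."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_examinations: int = 107
    n_patients: int = 48
    images_per_exam_mean: float = 336 / 107  # 1 + Poisson(mean - 1)
    # Fracture positivity clusters within examinations: an examination is
    # positive first, then its images are positive at the conditional rate
    # p_image_positive / p_examination_positive (at least one forced), so
    # both the positive-image and positive-examination totals are
    # reproduced in expectation.
    p_examination_positive: float = 65 / 107
    p_image_positive: float = 148 / 336
    fractures_per_positive_image_mean: float = 206 / 148  # 1 + Poisson(mean - 1)
    p_acute: float = 40 / 206
    image_width: float = 2000.0
    image_height: float = 2500.0
    box_size_min: float = 80.0
    box_size_max: float = 400.0
    p_male: float = 39 / 48
    p_upper_limb: float = 6 / 107
    p_lower_limb: float = 93 / 107
    p_pelvis: float = 8 / 107


class ReaderProfile(BaseModel):
    """Stochastic behaviour of one simulated radiologist."""

    model_config = ConfigDict(frozen=True)

    reader_id: str
    p_detect: float = Field(0.80, ge=0.0, le=1.0)  # per-fracture sensitivity
    fp_rate_per_image: float = Field(0.17, ge=0.0)  # Poisson mean
    localization_jitter: float = Field(0.08, ge=0.0)  # fraction of box side
    p_status_error: float = Field(0.30, ge=0.0, le=1.0)


class AIProfile(BaseModel):
    """Standalone AI reader: misses more fractures than the radiologists but
    places a similar number of stray boxes; no acute/healing capability."""

    model_config = ConfigDict(frozen=True)

    p_detect: float = Field(0.61, ge=0.0, le=1.0)
    fp_rate_per_image: float = Field(0.185, ge=0.0)
    localization_jitter: float = Field(0.08, ge=0.0)
    p_doubtful: float = Field(0.2, ge=0.0, le=1.0)  # certainty flag, analysis-inert


class Round2Behaviour(BaseModel):
    """How readers revise their round-1 calls after seeing the AI output."""

    model_config = ConfigDict(frozen=True)

    p_adopt_ai_when_disagree: float = Field(0.4, ge=0.0, le=1.0)
    p_spontaneous_flip: float = Field(0.03, ge=0.0, le=1.0)


def default_reader_profiles() -> list[ReaderProfile]:
    """Seven readers spread around 0.80 per-fracture sensitivity."""
    detects = [0.74, 0.77, 0.79, 0.80, 0.81, 0.83, 0.86]
    return [
        ReaderProfile(reader_id=f"R{i + 1}", p_detect=p) for i, p in enumerate(detects)
    ]


def _rng(seed: int, stream: str, key: str = "") -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [seed, zlib.crc32(stream.encode()), zlib.crc32(key.encode())]
        )
    )


def _sample_box(rng: np.random.Generator, cfg: SimulationConfig) -> BoundingBox:
    w = rng.uniform(cfg.box_size_min, cfg.box_size_max)
    h = rng.uniform(cfg.box_size_min, cfg.box_size_max)
    x = rng.uniform(0.0, cfg.image_width - w)
    y = rng.uniform(0.0, cfg.image_height - h)
    return BoundingBox(x_min=x, y_min=y, x_max=x + w, y_max=y + h)


def _disjoint(box: BoundingBox, others: Sequence[BoundingBox]) -> bool:
    return all(box.intersection_area(o) == 0.0 for o in others)


def _place_disjoint(
    rng: np.random.Generator, cfg: SimulationConfig, avoid: Sequence[BoundingBox], what: str
) -> BoundingBox:
    for _ in range(_PLACEMENT_RETRIES):
        box = _sample_box(rng, cfg)
        if _disjoint(box, avoid):
            return box
    raise RuntimeError(
        f"could not place a {what} box disjoint from {len(avoid)} existing "
        f"boxes on a {cfg.image_width}x{cfg.image_height} image after "
        f"{_PLACEMENT_RETRIES} attempts; reduce box sizes or fracture density"
    )


def _jitter_box(
    rng: np.random.Generator, box: BoundingBox, jitter: float, cfg: SimulationConfig
) -> BoundingBox:
    """Perturb centre (normal, sd = jitter * side) and log-size (sd = jitter)."""
    if jitter == 0.0:
        return box
    w, h = box.x_max - box.x_min, box.y_max - box.y_min
    cx = (box.x_min + box.x_max) / 2 + rng.normal(0.0, jitter * w)
    cy = (box.y_min + box.y_max) / 2 + rng.normal(0.0, jitter * h)
    w2 = w * float(np.exp(rng.normal(0.0, jitter)))
    h2 = h * float(np.exp(rng.normal(0.0, jitter)))
    x0 = float(np.clip(cx - w2 / 2, 0.0, cfg.image_width - 1.0))
    y0 = float(np.clip(cy - h2 / 2, 0.0, cfg.image_height - 1.0))
    x1 = float(np.clip(cx + w2 / 2, x0 + 1.0, cfg.image_width))
    y1 = float(np.clip(cy + h2 / 2, y0 + 1.0, cfg.image_height))
    return BoundingBox(x_min=x0, y_min=y0, x_max=x1, y_max=y1)


def _reader_status(rng: np.random.Generator, gt_status: str, p_error: float) -> str:
    if rng.random() < p_error:
        return "healing" if gt_status == "acute" else "acute"
    return gt_status


def generate_study(
    cfg: SimulationConfig = SimulationConfig(),
    reader_profiles: Optional[Sequence[ReaderProfile]] = None,
    ai_profile: AIProfile = AIProfile(),
    round2: Round2Behaviour = Round2Behaviour(),
    seed: Optional[int] = None,
) -> StudyDataset:
    """Generate a complete two-round study; deterministic given the seed.

    ``seed`` overrides ``cfg.seed`` when given.  ``reader_profiles`` may be
    any number of readers (default: seven spread around 0.80 sensitivity).
    """
    if reader_profiles is None:
        reader_profiles = default_reader_profiles()
    s = cfg.seed if seed is None else seed
    rng = _rng(s, "structure")

    patients = [
        PatientRecord(
            patient_id=f"P{i + 1:03d}",
            sex="male" if rng.random() < cfg.p_male else "female",
            age=float(rng.integers(6, 18)),
        )
        for i in range(cfg.n_patients)
    ]

    regions = ["upper_limb", "lower_limb", "pelvis"]
    region_p = np.array([cfg.p_upper_limb, cfg.p_lower_limb, cfg.p_pelvis])
    region_p = region_p / region_p.sum()

    examinations: list[ExaminationRecord] = []
    images: list[ImageRecord] = []
    gt_annotations: list[Annotation] = []
    gt_boxes_by_image: dict[str, list[tuple[BoundingBox, str]]] = {}

    img_counter = 0
    for e in range(cfg.n_examinations):
        exam_id = f"E{e + 1:03d}"
        patient = patients[e % cfg.n_patients]
        n_images = 1 + int(rng.poisson(max(cfg.images_per_exam_mean - 1, 0.0)))
        region = regions[int(rng.choice(3, p=region_p))]
        exam_positive = rng.random() < cfg.p_examination_positive
        q_image = (
            min(1.0, cfg.p_image_positive / cfg.p_examination_positive)
            if cfg.p_examination_positive > 0
            else 0.0
        )
        image_positive = [exam_positive and rng.random() < q_image for _ in range(n_images)]
        if exam_positive and not any(image_positive):
            image_positive[int(rng.integers(n_images))] = True
        image_ids = []
        for k in range(n_images):
            img_counter += 1
            iid = f"I{img_counter:04d}"
            image_ids.append(iid)
            images.append(
                ImageRecord(
                    image_id=iid,
                    examination_id=exam_id,
                    body_region=region,
                    width=cfg.image_width,
                    height=cfg.image_height,
                )
            )
            placed: list[tuple[BoundingBox, str]] = []
            if image_positive[k]:
                n_frac = 1 + int(
                    rng.poisson(max(cfg.fractures_per_positive_image_mean - 1, 0.0))
                )
                for _ in range(n_frac):
                    box = _place_disjoint(rng, cfg, [b for b, _ in placed], "ground-truth")
                    status = "acute" if rng.random() < cfg.p_acute else "healing"
                    placed.append((box, status))
                    gt_annotations.append(
                        Annotation(image_id=iid, source="ground_truth", box=box, status=status)
                    )
            gt_boxes_by_image[iid] = placed
        examinations.append(
            ExaminationRecord(
                examination_id=exam_id, patient_id=patient.patient_id, image_ids=tuple(image_ids)
            )
        )

    image_ids_all = [im.image_id for im in images]

    # AI reader: per-fracture detection + disjoint stray boxes.
    ai_rng = _rng(s, "ai")
    ai_annotations: list[Annotation] = []
    ai_detected: dict[str, set[int]] = {}
    ai_boxes: dict[str, dict[int, BoundingBox]] = {}
    ai_fp_boxes: dict[str, list[BoundingBox]] = {}
    for iid in image_ids_all:
        gt_here = gt_boxes_by_image[iid]
        det: set[int] = set()
        boxes: dict[int, BoundingBox] = {}
        for j, (gt_box, _) in enumerate(gt_here):
            if ai_rng.random() < ai_profile.p_detect:
                det.add(j)
                boxes[j] = _jitter_box(ai_rng, gt_box, ai_profile.localization_jitter, cfg)
        fps: list[BoundingBox] = []
        for _ in range(int(ai_rng.poisson(ai_profile.fp_rate_per_image))):
            fps.append(
                _place_disjoint(ai_rng, cfg, [b for b, _ in gt_here], "false-positive")
            )
        ai_detected[iid] = det
        ai_boxes[iid] = boxes
        ai_fp_boxes[iid] = fps
        for box in list(boxes.values()) + fps:
            certainty = "doubtful" if ai_rng.random() < ai_profile.p_doubtful else "certain"
            ai_annotations.append(
                Annotation(image_id=iid, source="ai", box=box, certainty=certainty)
            )

    # Readers, round 1 then round 2.
    reader_annotations: list[Annotation] = []
    for profile in reader_profiles:
        rid = profile.reader_id
        r1_rng = _rng(s, "reader:r1", rid)
        det1: dict[str, dict[int, tuple[BoundingBox, str]]] = {}
        fp1: dict[str, list[tuple[BoundingBox, str]]] = {}
        for iid in image_ids_all:
            gt_here = gt_boxes_by_image[iid]
            det_here: dict[int, tuple[BoundingBox, str]] = {}
            for j, (gt_box, gt_status) in enumerate(gt_here):
                if r1_rng.random() < profile.p_detect:
                    box = _jitter_box(r1_rng, gt_box, profile.localization_jitter, cfg)
                    status = _reader_status(r1_rng, gt_status, profile.p_status_error)
                    det_here[j] = (box, status)
            fps_here: list[tuple[BoundingBox, str]] = []
            for _ in range(int(r1_rng.poisson(profile.fp_rate_per_image))):
                box = _place_disjoint(r1_rng, cfg, [b for b, _ in gt_here], "false-positive")
                status = "acute" if r1_rng.random() < cfg.p_acute else "healing"
                fps_here.append((box, status))
            det1[iid] = det_here
            fp1[iid] = fps_here
            for box, status in list(det_here.values()) + fps_here:
                reader_annotations.append(
                    Annotation(
                        image_id=iid, source="reader", reader_id=rid, round="r1",
                        box=box, status=status,
                    )
                )

        r2_rng = _rng(s, "reader:r2", rid)
        for iid in image_ids_all:
            gt_here = gt_boxes_by_image[iid]
            det_here = dict(det1[iid])
            fps_here = list(fp1[iid])
            # fracture units
            for j, (gt_box, gt_status) in enumerate(gt_here):
                call1 = j in det_here
                ai_call = j in ai_detected[iid]
                flip = False
                adopt = False
                if call1 != ai_call and r2_rng.random() < round2.p_adopt_ai_when_disagree:
                    flip, adopt = True, True
                elif r2_rng.random() < round2.p_spontaneous_flip:
                    flip = True
                if not flip:
                    continue
                if call1:
                    det_here.pop(j)
                else:
                    if adopt:  # inherit the AI's box geometry
                        box = ai_boxes[iid][j]
                    else:
                        box = _jitter_box(r2_rng, gt_box, profile.localization_jitter, cfg)
                    status = _reader_status(r2_rng, gt_status, profile.p_status_error)
                    det_here[j] = (box, status)
            # FP-presence unit
            call1 = len(fps_here) > 0
            ai_call = len(ai_fp_boxes[iid]) > 0
            flip = False
            adopt = False
            if call1 != ai_call and r2_rng.random() < round2.p_adopt_ai_when_disagree:
                flip, adopt = True, True
            elif r2_rng.random() < round2.p_spontaneous_flip:
                flip = True
            if flip:
                if call1:
                    fps_here = []
                elif adopt:
                    fps_here = [
                        (b, "acute" if r2_rng.random() < cfg.p_acute else "healing")
                        for b in ai_fp_boxes[iid]
                    ]
                else:
                    box = _place_disjoint(r2_rng, cfg, [b for b, _ in gt_here], "false-positive")
                    fps_here = [(box, "acute" if r2_rng.random() < cfg.p_acute else "healing")]
            for box, status in list(det_here.values()) + fps_here:
                reader_annotations.append(
                    Annotation(
                        image_id=iid, source="reader", reader_id=rid, round="r2",
                        box=box, status=status,
                    )
                )

    return StudyDataset(
        patients=tuple(patients),
        examinations=tuple(examinations),
        images=tuple(images),
        annotations=tuple(gt_annotations + ai_annotations + reader_annotations),
    )


def threshold_sweep(
    ds: StudyDataset,
    thresholds: Sequence[float],
    mode: str = "gt_fraction",
    inclusive: bool = True,
):
    """Per-fracture TP/FP/FN for every source across overlap thresholds.

    Stands in for the unavailable derivation of the 40% operating point:
    shows how detection counts respond to the overlap convention.  TP is
    non-increasing in the threshold for every source.
    """
    import pandas as pd

    from .aggregation import fracture_level_counts
    from .matching import match_study

    if len(thresholds) == 0:
        raise ValueError("threshold sweep requires at least one threshold")
    sources: dict[str, list[Annotation]] = {"ai": ds.ai}
    for rid in ds.reader_ids:
        for rnd in ("r1", "r2"):
            sources[f"{rid}:{rnd}"] = ds.reader_annotations(rid, rnd)

    rows = []
    for t in thresholds:
        conv = OverlapConvention(mode=mode, threshold=float(t), inclusive=inclusive)
        for label, anns in sources.items():
            c = fracture_level_counts(ds, match_study(ds, anns, conv), label)
            rows.append(
                {"source": label, "threshold": float(t), "tp": c.tp, "fp": c.fp, "fn": c.fn}
            )
    return pd.DataFrame(rows)
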