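"""Fixation-to-landmark co-registration (nearest-landmark method).

Each fixation, on each frame it spans, is registered to the nearest
sufficiently-confident body or face landmark of any detected person,
provided the Euclidean pixel distance stays under a task-specific
threshold: 70 px for the navigation task (coarse, full-body detections) and
30 px for the face-to-face interaction task (dense facial landmarks).
Fixations with no landmark in range are labelled ``non_person``.

Body landmarks map to the two navigation-task categories (``head`` /
``body``); facial landmarks map to ``head`` in navigation mode or to one of
five facial regions (nose, left/right eye, mouth, face exterior) in
interaction mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .camera import CameraModel, px_to_deg
from .detections import (
    BODY_EAR_INDICES,
    BODY_HEAD_INDICES,
    FACE_JAW_ENDPOINTS,
    FACE_REGION_NAMES,
    N_BODY_KEYPOINTS,
    N_FACE_KEYPOINTS,
    BodyDetection,
    FaceDetection,
    FrameDetections,
    Keypoint,
    face_region_of,
)
from .fixation import FixationRecord

__all__ = [
    "RegistrationConfig",
    "FixationAssignment",
    "FaceVisibility",
    "filter_landmarks",
    "assign_fixation",
    "register_fixations",
    "classify_face_visibility",
    "head_width",
    "people_per_frame",
    "default_body_roi_map",
    "default_face_roi_map",
]

NON_PERSON = "non_person"


def default_body_roi_map() -> dict[int, str]:
    """Two-way head/body grouping of the 25 body keypoints."""
    return {
        i: ("head" if i in BODY_HEAD_INDICES else "body")
        for i in range(N_BODY_KEYPOINTS)
    }


def default_face_roi_map() -> dict[int, str]:
    """Five-way facial-region grouping of the 70 face keypoints."""
    return {i: face_region_of(i) for i in range(N_FACE_KEYPOINTS)}


@dataclass(frozen=True)
class RegistrationConfig:
    """Thresholds and ROI maps for nearest-landmark registration.

    ``confidence_min`` is a strict floor: only landmarks detected with
    confidence *greater than* this value survive filtering (screening out
    transient 'phantom' detections). ``face_roi_map=None`` means facial
    landmarks count as ``head`` (navigation mode); a five-region map
    switches the output labels to facial regions (interaction mode).
    """

    confidence_min: float = 0.6
    distance_threshold_px: float = 70.0
    body_roi_map: Mapping[int, str] = field(default_factory=default_body_roi_map)
    face_roi_map: Mapping[int, str] | None = None
    ear_indices: tuple[int, int] = BODY_EAR_INDICES

    def __post_init__(self) -> None:
        if self.distance_threshold_px <= 0:
            raise ValueError("distance_threshold_px must be positive")
        if set(self.body_roi_map) != set(range(N_BODY_KEYPOINTS)):
            raise ValueError("body_roi_map must cover indices 0..24 exactly")
        if not set(self.body_roi_map.values()) <= {"head", "body"}:
            raise ValueError("body ROI categories are 'head' and 'body'")
        if self.face_roi_map is not None:
            if set(self.face_roi_map) != set(range(N_FACE_KEYPOINTS)):
                raise ValueError("face_roi_map must cover indices 0..69 exactly")
            if not set(self.face_roi_map.values()) <= set(FACE_REGION_NAMES):
                raise ValueError(
                    f"face ROI categories must be among {FACE_REGION_NAMES}")

    @classmethod
    def navigation(cls, **overrides) -> "RegistrationConfig":
        """70 px threshold; facial landmarks labelled ``head``."""
        return cls(**{"distance_threshold_px": 70.0, **overrides})

    @classmethod
    def interaction(cls, **overrides) -> "RegistrationConfig":
        """30 px threshold; facial landmarks labelled by facial region."""
        defaults = {
            "distance_threshold_px": 30.0,
            "face_roi_map": default_face_roi_map(),
        }
        return cls(**{**defaults, **overrides})

    def roi_of(self, kind: str, landmark_index: int) -> str:
        if kind == "body":
            return self.body_roi_map[landmark_index]
        if kind == "face":
            if self.face_roi_map is None:
                return "head"
            return self.face_roi_map[landmark_index]
        raise ValueError(f"unknown landmark kind {kind!r}")


@dataclass(frozen=True)
class FixationAssignment:
    """One fixation x frame registered to a landmark (or to non_person)."""

    fixation_id: int
    frame_index: int
    roi: str
    person_index: int | None = None
    landmark_kind: str | None = None   # 'body' | 'face'
    landmark_index: int | None = None
    distance_px: float | None = None
    fix_x: float = math.nan
    fix_y: float = math.nan

    def __post_init__(self) -> None:
        if (self.roi == NON_PERSON) != (self.person_index is None):
            raise ValueError("roi is non_person iff person_index is None")

    @property
    def is_person(self) -> bool:
        return self.roi != NON_PERSON


@dataclass(frozen=True)
class FaceVisibility:
    """Full (all 70 landmarks detected) vs partial face visibility."""

    frame_index: int
    person_index: int
    status: str  # 'full' | 'partial'


def filter_landmarks(frame: FrameDetections,
                     config: RegistrationConfig) -> FrameDetections:
    """Drop landmarks at or below the confidence floor.

    Failing keypoints become ``present=False`` (the positional layout is
    fixed); detections left with no present keypoint are dropped entirely.
    """

    def _filter(det, cls):
        kps = [
            kp if (kp.present and kp.confidence > config.confidence_min)
            else Keypoint.missing()
            for kp in det.keypoints
        ]
        if not any(kp.present for kp in kps):
            return None
        return cls(kps, person_index=det.person_index)

    bodies = [b for b in (_filter(d, BodyDetection) for d in frame.bodies)
              if b is not None]
    faces = [f for f in (_filter(d, FaceDetection) for d in frame.faces)
             if f is not None]
    return FrameDetections(frame_index=frame.frame_index,
                           bodies=bodies, faces=faces)


def assign_fixation(fix: FixationRecord, frame: FrameDetections,
                    config: RegistrationConfig) -> FixationAssignment:
    """Register one fixation to the nearest present landmark in a frame.

    The frame must already be confidence-filtered. Ties are broken by
    person index, then body before face, then landmark index, for
    determinism. An empty frame or a nearest distance above the threshold
    yields a ``non_person`` assignment.
    """
    best = None  # (distance, person_index, kind_order, landmark_index, kind)
    for kind, pid, li, kp in frame.iter_present():
        d = math.hypot(kp.x - fix.x, kp.y - fix.y)
        key = (d, pid, 0 if kind == "body" else 1, li)
        if best is None or key < best[0]:
            best = (key, kind)
    if best is not None and best[0][0] <= config.distance_threshold_px:
        (d, pid, _, li), kind = best
        return FixationAssignment(
            fixation_id=fix.id, frame_index=frame.frame_index,
            roi=config.roi_of(kind, li), person_index=pid,
            landmark_kind=kind, landmark_index=li, distance_px=d,
            fix_x=fix.x, fix_y=fix.y,
        )
    return FixationAssignment(
        fixation_id=fix.id, frame_index=frame.frame_index, roi=NON_PERSON,
        fix_x=fix.x, fix_y=fix.y,
    )


def register_fixations(
    fixations: Sequence[FixationRecord],
    frames: Mapping[int, FrameDetections],
    config: RegistrationConfig,
    prefiltered: bool = False,
) -> list[FixationAssignment]:
    """Register every fixation on every frame it spans.

    A fixation spanning k frames contributes k assignments (one per
    fixation-frame); frames absent from ``frames`` are treated as having no
    detections. Returns assignments sorted by (fixation id, frame index).
    """
    cache: dict[int, FrameDetections] = {}
    out: list[FixationAssignment] = []
    for fix in fixations:
        for fi in sorted(fix.frame_indices):
            frame = frames.get(fi)
            if frame is None:
                frame = FrameDetections(frame_index=fi)
            elif not prefiltered:
                if fi not in cache:
                    cache[fi] = filter_landmarks(frame, config)
                frame = cache[fi]
            out.append(assign_fixation(fix, frame, config))
    return out


def classify_face_visibility(face: FaceDetection,
                             frame_index: int = -1) -> FaceVisibility:
    """Full iff all 70 facial keypoints were detected (raw presence,
    before any confidence filtering)."""
    n = face.n_present
    if n == 0:
        raise ValueError("a face detection must have at least one keypoint")
    status = "full" if n == N_FACE_KEYPOINTS else "partial"
    return FaceVisibility(frame_index=frame_index,
                          person_index=face.person_index, status=status)


def head_width(detection: BodyDetection | FaceDetection,
               camera: CameraModel,
               config: RegistrationConfig | None = None) -> float | None:
    """Ear-to-ear head width in degrees of visual angle, or None when an
    ear landmark is missing (unmeasurable).

    For body detections the ear keypoints are used; for face detections the
    jaw-contour endpoints (the landmarks nearest the ears).
    """
    if isinstance(detection, FaceDetection):
        ia, ib = FACE_JAW_ENDPOINTS
    else:
        ia, ib = (config.ear_indices if config is not None else BODY_EAR_INDICES)
    a, b = detection.keypoints[ia], detection.keypoints[ib]
    if not (a.present and b.present):
        return None
    return px_to_deg(math.hypot(a.x - b.x, a.y - b.y), camera)


def people_per_frame(frames: Iterable[FrameDetections]) -> float:
    """Mean number of detected persons per frame."""
    counts = [f.n_persons for f in frames]
    if not counts:
        raise ValueError("people_per_frame requires at least one frame")
    return float(np.mean(counts))
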