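"""Per-frame person detections: body and face landmark containers.

The containers mirror the BODY_25 (25 body keypoints) and 70-point face
layouts emitted by multi-person pose detectors. A missing keypoint is the
(0, 0, 0) sentinel triplet in the raw output and is carried here as
``present=False`` so that it can never win a nearest-landmark search at the
image origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "Keypoint",
    "BodyDetection",
    "FaceDetection",
    "FrameDetections",
    "N_BODY_KEYPOINTS",
    "N_FACE_KEYPOINTS",
    "BODY25_NAMES",
    "BODY_HEAD_INDICES",
    "BODY_EAR_INDICES",
    "FACE_JAW_ENDPOINTS",
    "FACE_REGIONS",
    "FACE_REGION_NAMES",
    "face_region_of",
]

N_BODY_KEYPOINTS = 25
N_FACE_KEYPOINTS = 70

BODY25_NAMES = (
    "nose", "neck",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
    "mid_hip", "r_hip", "r_knee", "r_ankle",
    "l_hip", "l_knee", "l_ankle",
    "r_eye", "l_eye", "r_ear", "l_ear",
    "l_big_toe", "l_small_toe", "l_heel",
    "r_big_toe", "r_small_toe", "r_heel",
)

# Head category of the 25-point body model: nose, neck, eyes and ears.
BODY_HEAD_INDICES = frozenset({0, 1, 15, 16, 17, 18})
BODY_EAR_INDICES = (17, 18)

# Jaw contour endpoints of the 70-point face model (ear-to-ear extremes).
FACE_JAW_ENDPOINTS = (0, 16)

# Five-way grouping of the 70 facial landmarks. Indices follow the standard
# 68-point layout (jaw 0-16, brows 17-26, nose 27-35, eyes 36-47, lips
# 48-67) plus the two pupil points 68/69. "left"/"right" are the image's
# left/right (viewer perspective), matching the detector output.
FACE_REGIONS: dict[str, frozenset[int]] = {
    "face_exterior": frozenset(range(0, 27)),  # jaw contour + both brows
    "nose": frozenset(range(27, 36)),
    "left_eye": frozenset(range(36, 42)) | frozenset({68}),
    "right_eye": frozenset(range(42, 48)) | frozenset({69}),
    "mouth": frozenset(range(48, 68)),
}
FACE_REGION_NAMES = ("nose", "left_eye", "right_eye", "mouth", "face_exterior")

_FACE_REGION_OF_INDEX = {
    idx: name for name, idxs in FACE_REGIONS.items() for idx in idxs
}


def face_region_of(landmark_index: int) -> str:
    """Facial region name for a 70-point face landmark index."""
    return _FACE_REGION_OF_INDEX[landmark_index]


@dataclass(frozen=True)
class Keypoint:
    """One detected landmark: pixel position plus detector confidence."""

    x: float
    y: float
    confidence: float
    present: bool = True

    @classmethod
    def from_triplet(cls, x: float, y: float, confidence: float) -> "Keypoint":
        present = not (x == 0.0 and y == 0.0 and confidence == 0.0)
        return cls(x=x, y=y, confidence=confidence, present=present)

    @classmethod
    def missing(cls) -> "Keypoint":
        return cls(0.0, 0.0, 0.0, present=False)


@dataclass
class _Detection:
    keypoints: list[Keypoint]
    person_index: int
    _expected: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self._expected and len(self.keypoints) != self._expected:
            raise ValueError(
                f"expected {self._expected} keypoints, got {len(self.keypoints)}"
            )

    @property
    def n_present(self) -> int:
        return sum(kp.present for kp in self.keypoints)

    def present_indices(self) -> list[int]:
        return [i for i, kp in enumerate(self.keypoints) if kp.present]

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of all keypoint positions (missing ones included)."""
        return np.array([[kp.x, kp.y] for kp in self.keypoints], dtype=float)


@dataclass
class BodyDetection(_Detection):
    def __post_init__(self) -> None:
        self._expected = N_BODY_KEYPOINTS
        super().__post_init__()


@dataclass
class FaceDetection(_Detection):
    def __post_init__(self) -> None:
        self._expected = N_FACE_KEYPOINTS
        super().__post_init__()


@dataclass
class FrameDetections:
    """All person detections in one video frame."""

    frame_index: int
    bodies: list[BodyDetection] = field(default_factory=list)
    faces: list[FaceDetection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        for group in (self.bodies, self.faces):
            idxs = [d.person_index for d in group]
            if len(idxs) != len(set(idxs)):
                raise ValueError("person_index values must be unique within a frame")

    @property
    def n_persons(self) -> int:
        ids = {d.person_index for d in self.bodies} | {
            d.person_index for d in self.faces
        }
        return len(ids)

    @property
    def is_empty(self) -> bool:
        return not self.bodies and not self.faces

    def iter_present(self) -> Iterator[tuple[str, int, int, Keypoint]]:
        """Yield (kind, person_index, landmark_index, keypoint) for every
        present keypoint, bodies first, in stable index order."""
        for det in self.bodies:
            for i, kp in enumerate(det.keypoints):
                if kp.present:
                    yield "body", det.person_index, i, kp
        for det in self.faces:
            for i, kp in enumerate(det.keypoints):
                if kp.present:
                    yield "face", det.person_index, i, kp
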