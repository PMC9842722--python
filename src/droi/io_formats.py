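"""File dialects: pose-detector keypoint JSON, gaze/fixation CSV, embeddings.

The keypoint JSON dialect is the one-file-per-frame format written by
OpenPose: a ``people`` array in which each person carries flattened
``(x, y, confidence)`` triplets under ``pose_keypoints_2d`` (75 numbers)
and, when the face was close enough to resolve, ``face_keypoints_2d``
(210 numbers). Missing keypoints are ``(0, 0, 0)`` triplets.

Gaze CSVs come in tracker dialects that differ in the origin of the
normalized coordinate frame. The Pupil export convention puts the origin at
the *bottom*-left; this package's convention is top-left, y down, so the
``pupil`` dialect applies ``y -> 1 - y`` on read and write.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .camera import CameraModel
from .detections import (
    N_BODY_KEYPOINTS,
    N_FACE_KEYPOINTS,
    BodyDetection,
    FaceDetection,
    FrameDetections,
    Keypoint,
)

__all__ = [
    "FormatError",
    "GazeSample",
    "read_openpose_frame",
    "write_openpose_frame",
    "read_openpose_dir",
    "write_openpose_dir",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_fixation_csv",
    "write_fixation_csv",
    "read_embeddings_csv",
    "write_embeddings_csv",
    "read_landmark_sidecar",
    "write_landmark_sidecar",
    "GAZE_COLUMNS",
    "PUPIL_GAZE_COLUMNS",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class GazeSample:
    """One gaze datum in normalized top-left coordinates.

    ``x`` and ``y`` are in [0, 1] relative to the scene-camera frame with
    the package convention (origin top-left, y down); ``confidence`` is the
    tracker's pupil-detection confidence.
    """

    timestamp: float
    frame_index: int
    x: float
    y: float
    confidence: float = 1.0

    def to_px(self, camera: CameraModel) -> tuple[float, float]:
        return camera.norm_to_px(self.x, self.y)


# ---------------------------------------------------------------------------
# keypoint JSON


def _triplets_to_keypoints(flat: Sequence[float], n_expected: int,
                           field: str, source: str) -> list[Keypoint]:
    if len(flat) != 3 * n_expected:
        raise FormatError(
            f"{source}: field '{field}' has {len(flat)} numbers, "
            f"expected {3 * n_expected} (= {n_expected} x,y,c triplets)"
        )
    return [
        Keypoint.from_triplet(flat[3 * i], flat[3 * i + 1], flat[3 * i + 2])
        for i in range(n_expected)
    ]


def read_openpose_frame(json_text: str | bytes | dict, frame_index: int = 0,
                        source: str = "<string>") -> FrameDetections:
    """Parse one per-frame keypoint JSON document.

    Emits one :class:`BodyDetection` per entry of the ``people`` array and a
    :class:`FaceDetection` only for entries that carry face triplets.
    ``(0,0,0)`` triplets become ``present=False`` keypoints.
    """
    if isinstance(json_text, dict):
        doc = json_text
    else:
        try:
            doc = json.loads(json_text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{source}: malformed JSON ({exc})") from exc
    if not isinstance(doc, dict) or "people" not in doc:
        raise FormatError(f"{source}: missing 'people' array")
    people = doc["people"]
    if not isinstance(people, list):
        raise FormatError(f"{source}: 'people' is not an array")

    bodies: list[BodyDetection] = []
    faces: list[FaceDetection] = []
    for pid, person in enumerate(people):
        pose = person.get("pose_keypoints_2d")
        if pose is None:
            raise FormatError(
                f"{source}: person {pid} lacks 'pose_keypoints_2d'"
            )
        bodies.append(BodyDetection(
            _triplets_to_keypoints(pose, N_BODY_KEYPOINTS,
                                   "pose_keypoints_2d", source),
            person_index=pid,
        ))
        face = person.get("face_keypoints_2d")
        if face:  # absent or empty list -> no face detection
            faces.append(FaceDetection(
                _triplets_to_keypoints(face, N_FACE_KEYPOINTS,
                                       "face_keypoints_2d", source),
                person_index=pid,
            ))
    return FrameDetections(frame_index=frame_index, bodies=bodies, faces=faces)


def write_openpose_frame(frame: FrameDetections) -> str:
    """Serialize detections back into the per-frame keypoint JSON dialect."""
    faces_by_pid = {f.person_index: f for f in frame.faces}
    people = []
    for body in frame.bodies:
        entry: dict = {"pose_keypoints_2d": _keypoints_to_flat(body.keypoints)}
        face = faces_by_pid.get(body.person_index)
        if face is not None:
            entry["face_keypoints_2d"] = _keypoints_to_flat(face.keypoints)
        people.append(entry)
    # faces without a body (unusual but legal) get zeroed pose triplets
    body_pids = {b.person_index for b in frame.bodies}
    for face in frame.faces:
        if face.person_index not in body_pids:
            people.append({
                "pose_keypoints_2d": [0.0] * (3 * N_BODY_KEYPOINTS),
                "face_keypoints_2d": _keypoints_to_flat(face.keypoints),
            })
    return json.dumps({"version": 1.3, "people": people})


def _keypoints_to_flat(keypoints: Sequence[Keypoint]) -> list[float]:
    flat: list[float] = []
    for kp in keypoints:
        if kp.present:
            flat.extend((kp.x, kp.y, kp.confidence))
        else:
            flat.extend((0.0, 0.0, 0.0))
    return flat


def read_openpose_dir(directory: str | Path) -> dict[int, FrameDetections]:
    """Read a directory of ``frame_<n>.json`` files into a frame map."""
    out: dict[int, FrameDetections] = {}
    for path in sorted(Path(directory).glob("*.json")):
        digits = "".join(ch for ch in path.stem if ch.isdigit())
        if not digits:
            raise FormatError(f"{path}: cannot infer frame index from name")
        idx = int(digits)
        out[idx] = read_openpose_frame(path.read_text(), frame_index=idx,
                                       source=str(path))
    return out


def write_openpose_dir(frames: Iterable[FrameDetections],
                       directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in frames:
        path = directory / f"frame_{frame.frame_index:06d}.json"
        path.write_text(write_openpose_frame(frame))


# ---------------------------------------------------------------------------
# gaze CSV

GAZE_COLUMNS = {
    "timestamp": "timestamp",
    "frame_index": "frame_index",
    "x": "norm_x",
    "y": "norm_y",
    "confidence": "confidence",
}

PUPIL_GAZE_COLUMNS = {
    "timestamp": "gaze_timestamp",
    "frame_index": "world_index",
    "x": "norm_pos_x",
    "y": "norm_pos_y",
    "confidence": "confidence",
}


def _resolve_columns(dialect: str, column_map: dict | None) -> dict:
    if column_map is not None:
        cols = dict(column_map)
    elif dialect == "pupil":
        cols = dict(PUPIL_GAZE_COLUMNS)
    else:
        cols = dict(GAZE_COLUMNS)
    missing = set(GAZE_COLUMNS) - set(cols)
    if missing:
        raise FormatError(f"column map lacks keys: {sorted(missing)}")
    return cols


def read_gaze_csv(path, dialect: str = "topleft",
                  column_map: dict | None = None) -> list[GazeSample]:
    """Read a gaze stream CSV.

    ``dialect="pupil"`` reads bottom-left-origin normalized coordinates and
    flips them into the package's top-left convention; ``"topleft"`` reads
    coordinates as-is. Non-monotone timestamps trigger a warning and a
    stable sort.
    """
    if dialect not in ("topleft", "pupil"):
        raise ValueError(f"unknown gaze dialect: {dialect!r}")
    cols = _resolve_columns(dialect, column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gaze columns {missing}")
    ts = df[cols["timestamp"]].to_numpy(dtype=float)
    if np.any(np.diff(ts) < 0):
        warnings.warn(f"{path}: timestamps not monotone; applying stable sort")
        df = df.iloc[np.argsort(ts, kind="stable")].reset_index(drop=True)
    y = df[cols["y"]].to_numpy(dtype=float)
    if dialect == "pupil":
        y = 1.0 - y
    return [
        GazeSample(
            timestamp=float(t),
            frame_index=int(f),
            x=float(x),
            y=float(yy),
            confidence=float(c),
        )
        for t, f, x, yy, c in zip(
            df[cols["timestamp"]], df[cols["frame_index"]],
            df[cols["x"]], y, df[cols["confidence"]],
        )
    ]


def write_gaze_csv(samples: Sequence[GazeSample], path,
                   dialect: str = "topleft",
                   column_map: dict | None = None) -> None:
    if dialect not in ("topleft", "pupil"):
        raise ValueError(f"unknown gaze dialect: {dialect!r}")
    cols = _resolve_columns(dialect, column_map)
    y = np.array([s.y for s in samples], dtype=float)
    if dialect == "pupil":
        y = 1.0 - y
    df = pd.DataFrame({
        cols["timestamp"]: [s.timestamp for s in samples],
        cols["frame_index"]: [s.frame_index for s in samples],
        cols["x"]: [s.x for s in samples],
        cols["y"]: y,
        cols["confidence"]: [s.confidence for s in samples],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixation CSV

_FIXATION_COLUMNS = ["id", "start_ts", "duration_ms", "x_px", "y_px",
                     "dispersion_deg", "frames"]


def write_fixation_csv(fixations, path) -> None:
    """Write detected fixations; ``frames`` is a ;-joined frame-index list."""
    rows = [{
        "id": f.id,
        "start_ts": f.start_ts,
        "duration_ms": f.duration_ms,
        "x_px": f.x,
        "y_px": f.y,
        "dispersion_deg": f.dispersion_deg,
        "frames": ";".join(str(i) for i in sorted(f.frame_indices)),
    } for f in fixations]
    pd.DataFrame(rows, columns=_FIXATION_COLUMNS).to_csv(path, index=False)


def read_fixation_csv(path):
    from .fixation import FixationRecord  # deferred to avoid cycle

    df = pd.read_csv(path)
    missing = [c for c in _FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing fixation columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        frames = frozenset(int(t) for t in str(row.frames).split(";") if t != "")
        out.append(FixationRecord(
            id=int(row.id), start_ts=float(row.start_ts),
            duration_ms=float(row.duration_ms), x=float(row.x_px),
            y=float(row.y_px), dispersion_deg=float(row.dispersion_deg),
            frame_indices=frames,
        ))
    return out


# ---------------------------------------------------------------------------
# embeddings CSV and landmark sidecars


def write_embeddings_csv(crop_ids: Sequence, vectors: np.ndarray, path) -> None:
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or len(crop_ids) != vectors.shape[0]:
        raise ValueError("vectors must be (n_crops, dim)")
    df = pd.DataFrame(vectors,
                      columns=[f"v{i + 1}" for i in range(vectors.shape[1])])
    df.insert(0, "crop_id", list(crop_ids))
    df.to_csv(path, index=False)


def read_embeddings_csv(path) -> tuple[list, np.ndarray]:
    """Returns (crop_ids, (n, d) embedding matrix)."""
    df = pd.read_csv(path)
    if "crop_id" not in df.columns:
        raise FormatError(f"{path}: missing 'crop_id' column")
    vcols = [c for c in df.columns if c != "crop_id"]
    if not vcols:
        raise FormatError(f"{path}: no embedding columns")
    mat = df[vcols].to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise FormatError(f"{path}: non-finite embedding values")
    return list(df["crop_id"]), mat


def write_landmark_sidecar(landmarks: np.ndarray, path) -> None:
    """70-point landmark sidecar for a face crop, in crop pixel coordinates."""
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.shape != (N_FACE_KEYPOINTS, 2):
        raise ValueError(f"landmarks must be ({N_FACE_KEYPOINTS}, 2)")
    pd.DataFrame({"x": landmarks[:, 0], "y": landmarks[:, 1]}).to_csv(
        path, index=False)


def read_landmark_sidecar(path) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["x", "y"] or len(df) != N_FACE_KEYPOINTS:
        raise FormatError(
            f"{path}: expected {N_FACE_KEYPOINTS} rows of x,y")
    return df.to_numpy(dtype=float)
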