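"""Ground-truthed synthetic scenes for exercising the whole pipeline.

The generator emulates the two recording situations the pipeline analyses:

* a *navigation* scene — several pedestrians with 25-point stick-figure
  skeletons (plus 70-point faces when close enough) move on linear
  trajectories across a 1920x1080, 60 fps scene camera, while the gaze
  stream alternates planted fixations (on a head landmark, a body landmark
  or a background point, drawn from a configurable policy) with fast
  saccades; and
* a *face-to-face interaction* scene — a single large frontal face with
  small per-frame jitter, with fixations planted on facial-region
  landmarks.

Gaze noise is specified in degrees of visual angle and converted to pixels
through the camera model, mirroring how tracker accuracy is quoted.
Every planted fixation's true label, target and timing are returned as
ground truth, which is what makes parameter-recovery testing possible.
Geometry is metrically faithful; photorealism is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import CameraModel, deg_to_px
from .detections import (
    FACE_REGIONS,
    FACE_REGION_NAMES,
    N_BODY_KEYPOINTS,
    N_FACE_KEYPOINTS,
    BodyDetection,
    FaceDetection,
    FrameDetections,
    Keypoint,
)
from .face_template import default_template_landmarks
from .io_formats import GazeSample, write_gaze_csv, write_openpose_dir

__all__ = [
    "SceneConfig",
    "InteractionConfig",
    "PlantedFixation",
    "GroundTruth",
    "SyntheticScene",
    "generate_navigation_scene",
    "generate_interaction_scene",
    "generate_identity_embeddings",
    "generate_split_half_participants",
    "write_scene",
    "CANONICAL_BODY25",
]

# Canonical stick figure: BODY_25 keypoints in units of body height,
# x right / y down, head top at y=0, heels near y=1. Metric plausibility is
# what matters (landmark spacing scales with simulated distance).
CANONICAL_BODY25 = np.array([
    (0.000, 0.060),   # 0  nose
    (0.000, 0.150),   # 1  neck
    (-0.110, 0.160),  # 2  r_shoulder
    (-0.140, 0.300),  # 3  r_elbow
    (-0.150, 0.440),  # 4  r_wrist
    (0.110, 0.160),   # 5  l_shoulder
    (0.140, 0.300),   # 6  l_elbow
    (0.150, 0.440),   # 7  l_wrist
    (0.000, 0.500),   # 8  mid_hip
    (-0.060, 0.500),  # 9  r_hip
    (-0.070, 0.730),  # 10 r_knee
    (-0.070, 0.960),  # 11 r_ankle
    (0.060, 0.500),   # 12 l_hip
    (0.070, 0.730),   # 13 l_knee
    (0.070, 0.960),   # 14 l_ankle
    (-0.025, 0.045),  # 15 r_eye
    (0.025, 0.045),   # 16 l_eye
    (-0.050, 0.055),  # 17 r_ear
    (0.050, 0.055),   # 18 l_ear
    (0.090, 1.000),   # 19 l_big_toe
    (0.110, 0.995),   # 20 l_small_toe
    (0.065, 0.990),   # 21 l_heel
    (-0.090, 1.000),  # 22 r_big_toe
    (-0.110, 0.995),  # 23 r_small_toe
    (-0.065, 0.990),  # 24 r_heel
])

_HEAD_TARGETS = (0, 15, 16, 17, 18)          # nose, eyes, ears
_BODY_TARGETS = (3, 4, 6, 7, 8, 10, 13)      # limbs and hip, away from head


@dataclass(frozen=True)
class SceneConfig:
    """Navigation-scene parameters.

    The gaze policy defaults (head 4.3%, body 11.6%, background 84.1%)
    reproduce the attention rates observed when adults navigate a busy
    public space; durations, the 0.1 degree deposit noise (well inside the
    0.6 degree accuracy of wearable trackers) and the 60 fps 1920x1080
    camera match the recording setup the pipeline targets.
    """

    n_fixations: int = 100
    camera: CameraModel = field(default_factory=CameraModel)
    gaze_hz: float = 120.0
    n_persons: int = 3
    person_height_px: tuple[float, float] = (300.0, 700.0)
    person_speed_px: float = 1.2          # max |velocity| per frame and axis
    p_head: float = 0.043
    p_body: float = 0.116
    p_background: float = 0.841
    fixation_duration_ms: tuple[float, float] = (100.0, 200.0)
    saccade_ms: float = 40.0
    gaze_noise_deg: float = 0.1
    min_jump_deg: float = 3.5
    confidence_range: tuple[float, float] = (0.7, 1.0)
    low_confidence_rate: float = 0.03
    occlusion_rate: float = 0.2
    face_min_height_px: float = 400.0
    background_margin_px: float = 175.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.p_head + self.p_body + self.p_background - 1.0) > 1e-9:
            raise ValueError("gaze policy probabilities must sum to 1")
        if self.n_persons == 0 and self.p_head + self.p_body > 0:
            raise ValueError("person-directed gaze requires persons > 0")
        if self.n_fixations < 1:
            raise ValueError("n_fixations must be positive")


@dataclass(frozen=True)
class InteractionConfig:
    """Face-to-face interaction parameters.

    One full 70-landmark frontal face subtending ``face_width_deg``
    ear-to-ear (default 8.2 degrees, a conversation-distance face) with
    small per-frame jitter; fixations target facial regions per
    ``region_probs``.
    """

    n_fixations: int = 200
    camera: CameraModel = field(default_factory=CameraModel)
    gaze_hz: float = 120.0
    face_width_deg: float = 8.2
    jitter_px: float = 1.0
    region_probs: tuple[float, float, float, float, float] = (
        0.35, 0.20, 0.20, 0.15, 0.10)      # nose, L eye, R eye, mouth, ext.
    p_background: float = 0.05
    fixation_duration_ms: tuple[float, float] = (100.0, 200.0)
    saccade_ms: float = 40.0
    gaze_noise_deg: float = 0.1
    confidence_range: tuple[float, float] = (0.8, 1.0)
    background_margin_px: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.region_probs) - 1.0) > 1e-9:
            raise ValueError("region_probs must sum to 1")
        if not 0.0 <= self.p_background < 1.0:
            raise ValueError("p_background must lie in [0, 1)")


@dataclass(frozen=True)
class PlantedFixation:
    """Ground truth for one planted fixation."""

    label: str                       # 'head' | 'body' | 'background' | region
    onset: float                     # seconds
    duration_ms: float
    x_px: float                      # target position at onset
    y_px: float
    person_index: int | None = None
    landmark_kind: str | None = None  # 'body' | 'face'
    landmark_index: int | None = None


@dataclass(frozen=True)
class GroundTruth:
    fixations: tuple[PlantedFixation, ...]
    face_visibility: dict[tuple[int, int], str] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticScene:
    frames: tuple[FrameDetections, ...]
    gaze: tuple[GazeSample, ...]
    truth: GroundTruth
    camera: CameraModel

    @property
    def frame_map(self) -> dict[int, FrameDetections]:
        return {f.frame_index: f for f in self.frames}


def _scaled_face(height_px: float) -> np.ndarray:
    """Template landmarks scaled onto a stick figure of given height,
    relative to the figure anchor (head-top), in pixels."""
    tpl = default_template_landmarks()
    scale = (0.10 * height_px) / 160.0   # ear-to-ear = head width = 0.10 h
    out = (tpl - np.array([100.0, 82.0])) * scale
    out[:, 1] += 0.045 * height_px       # align pupil line with eye height
    return out


def _simulate_positions(rng, config: SceneConfig, n_frames: int,
                        heights: np.ndarray) -> np.ndarray:
    """(n_persons, n_frames, 2) anchor positions, reflecting at margins."""
    cam = config.camera
    pos = np.zeros((config.n_persons, n_frames, 2))
    for p in range(config.n_persons):
        h = heights[p]
        x = rng.uniform(0.25 * cam.width, 0.75 * cam.width)
        y = rng.uniform(0.0, max(1.0, cam.height - h))
        vx, vy = rng.uniform(-config.person_speed_px,
                             config.person_speed_px, size=2)
        vy *= 0.25  # pedestrians mostly translate horizontally
        lo_x, hi_x = 0.18 * cam.width, 0.82 * cam.width
        lo_y, hi_y = 0.0, max(1.0, cam.height - h)
        for f in range(n_frames):
            pos[p, f] = (x, y)
            x += vx
            y += vy
            if x < lo_x or x > hi_x:
                vx = -vx
                x = min(max(x, lo_x), hi_x)
            if y < lo_y or y > hi_y:
                vy = -vy
                y = min(max(y, lo_y), hi_y)
    return pos


def generate_navigation_scene(config: SceneConfig | None = None
                              ) -> SyntheticScene:
    """Generate a navigation scene with planted head/body/background
    fixations and full ground truth. Deterministic under a fixed seed."""
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    cam = config.camera

    # timeline: durations first, so the frame budget is known up front
    durations_ms = rng.uniform(*config.fixation_duration_ms,
                               size=config.n_fixations)
    total_s = float(durations_ms.sum() / 1000.0
                    + config.n_fixations * config.saccade_ms / 1000.0) + 0.5
    n_frames = int(math.ceil(total_s * cam.fps)) + 1

    heights = rng.uniform(*config.person_height_px, size=max(config.n_persons, 1))
    pos = _simulate_positions(rng, config, n_frames, heights)
    has_face = heights >= config.face_min_height_px

    def landmarks_at(p: int, f: int) -> tuple[np.ndarray, np.ndarray | None]:
        body = CANONICAL_BODY25 * heights[p] + pos[p, f]
        face = (_scaled_face(heights[p]) + pos[p, f]) if has_face[p] else None
        return body, face

    def all_points_at(f: int) -> np.ndarray:
        pts = []
        for p in range(config.n_persons):
            body, face = landmarks_at(p, f)
            pts.append(body)
            if face is not None:
                pts.append(face)
        return np.vstack(pts) if pts else np.zeros((0, 2))

    noise_px = deg_to_px(config.gaze_noise_deg, cam) if config.gaze_noise_deg else 0.0
    min_jump_px = deg_to_px(config.min_jump_deg, cam)
    dt = 1.0 / config.gaze_hz
    labels = rng.choice(
        ["head", "body", "background"], size=config.n_fixations,
        p=[config.p_head, config.p_body, config.p_background])

    gaze: list[GazeSample] = []
    planted: list[PlantedFixation] = []
    t = 0.1
    prev_point = np.array([cam.width / 2.0, cam.height / 2.0])

    def frame_of(tt: float) -> int:
        return min(int(tt * cam.fps), n_frames - 1)

    for k in range(config.n_fixations):
        label = labels[k]
        dur_s = durations_ms[k] / 1000.0
        f_on = frame_of(t)
        f_off = frame_of(t + dur_s)

        target_person = target_kind = target_index = None
        for _try in range(60):
            if label == "head":
                target_person = int(rng.integers(config.n_persons))
                target_index = int(rng.choice(_HEAD_TARGETS))
                target_kind = "body"
            elif label == "body":
                target_person = int(rng.integers(config.n_persons))
                target_index = int(rng.choice(_BODY_TARGETS))
                target_kind = "body"
            else:
                cand = np.array([
                    rng.uniform(0.05 * cam.width, 0.95 * cam.width),
                    rng.uniform(0.05 * cam.height, 0.95 * cam.height),
                ])
                clear = True
                for f in range(f_on, f_off + 1):
                    pts = all_points_at(f)
                    if len(pts) and np.min(
                            np.hypot(*(pts - cand).T)) < config.background_margin_px:
                        clear = False
                        break
                if not clear:
                    continue
            point0 = (cand if label == "background"
                      else _target_pos(target_person, target_index,
                                       landmarks_at, f_on))
            if np.hypot(*(point0 - prev_point)) >= min_jump_px:
                break
        # saccade samples from prev_point to the new target
        n_sac = max(int(config.saccade_ms / 1000.0 / dt), 2)
        for s in range(n_sac):
            frac = (s + 1) / (n_sac + 1)
            xy = prev_point + frac * (point0 - prev_point)
            ts = t - config.saccade_ms / 1000.0 + s * dt
            if ts < 0:
                continue
            gaze.append(_sample(ts, xy, cam, frame_of(ts), rng,
                                config.confidence_range))
        # dwell samples track the (possibly moving) target
        n_dwell = int(dur_s / dt) + 1
        for s in range(n_dwell):
            ts = t + s * dt
            f = frame_of(ts)
            if label == "background":
                xy = point0.copy()
            else:
                xy = _target_pos(target_person, target_index, landmarks_at, f)
            if noise_px:
                xy = xy + rng.normal(0.0, noise_px, size=2)
            gaze.append(_sample(ts, xy, cam, f, rng, config.confidence_range))
        planted.append(PlantedFixation(
            label=label, onset=t, duration_ms=float(durations_ms[k]),
            x_px=float(point0[0]), y_px=float(point0[1]),
            person_index=target_person, landmark_kind=target_kind,
            landmark_index=target_index,
        ))
        prev_point = (point0 if label == "background"
                      else _target_pos(target_person, target_index,
                                       landmarks_at, f_off))
        t += dur_s + config.saccade_ms / 1000.0

    frames, visibility = _build_frames(rng, config, n_frames, heights,
                                       has_face, landmarks_at)
    gaze.sort(key=lambda s: s.timestamp)  # guard against float round-off
    return SyntheticScene(
        frames=tuple(frames), gaze=tuple(gaze),
        truth=GroundTruth(fixations=tuple(planted),
                          face_visibility=visibility),
        camera=cam,
    )


def _target_pos(p, idx, landmarks_at, f) -> np.ndarray:
    body, _face = landmarks_at(p, f)
    return body[idx].copy()


def _sample(ts, xy, cam: CameraModel, frame: int, rng,
            conf_range) -> GazeSample:
    return GazeSample(
        timestamp=float(ts), frame_index=int(frame),
        x=float(xy[0] / cam.width), y=float(xy[1] / cam.height),
        confidence=float(rng.uniform(max(conf_range[0], 0.85), conf_range[1])),
    )


def _confidences(rng, n, config) -> np.ndarray:
    conf = rng.uniform(*config.confidence_range, size=n)
    low = rng.random(n) < config.low_confidence_rate
    conf[low] = rng.uniform(0.2, 0.6, size=int(low.sum()))
    return conf


def _build_frames(rng, config: SceneConfig, n_frames, heights, has_face,
                  landmarks_at):
    frames: list[FrameDetections] = []
    visibility: dict[tuple[int, int], str] = {}
    for f in range(n_frames):
        bodies, faces = [], []
        for p in range(config.n_persons):
            body_pts, face_pts = landmarks_at(p, f)
            conf = _confidences(rng, N_BODY_KEYPOINTS, config)
            bodies.append(BodyDetection(
                [Keypoint(float(x), float(y), float(c))
                 for (x, y), c in zip(body_pts, conf)],
                person_index=p,
            ))
            if face_pts is None:
                continue
            conf = _confidences(rng, N_FACE_KEYPOINTS, config)
            occluded = rng.random() < config.occlusion_rate
            drop = set()
            if occluded:
                n_drop = int(rng.integers(1, 25))
                drop = set(rng.choice(N_FACE_KEYPOINTS, size=n_drop,
                                      replace=False).tolist())
            kps = [
                Keypoint.missing() if i in drop
                else Keypoint(float(x), float(y), float(c))
                for i, ((x, y), c) in enumerate(zip(face_pts, conf))
            ]
            faces.append(FaceDetection(kps, person_index=p))
            visibility[(f, p)] = "partial" if drop else "full"
        frames.append(FrameDetections(frame_index=f, bodies=bodies,
                                      faces=faces))
    return frames, visibility


def generate_interaction_scene(config: InteractionConfig | None = None
                               ) -> SyntheticScene:
    """Generate a face-to-face interaction scene: one large frontal face
    with per-frame jitter and fixations planted on facial regions."""
    config = config or InteractionConfig()
    rng = np.random.default_rng(config.seed)
    cam = config.camera

    durations_ms = rng.uniform(*config.fixation_duration_ms,
                               size=config.n_fixations)
    total_s = float(durations_ms.sum() / 1000.0
                    + config.n_fixations * config.saccade_ms / 1000.0) + 0.5
    n_frames = int(math.ceil(total_s * cam.fps)) + 1

    tpl = default_template_landmarks()
    width_px = deg_to_px(config.face_width_deg, cam)
    scale = width_px / 160.0             # jaw ear-to-ear span in template units
    base = (tpl - np.array([100.0, 110.0])) * scale \
        + np.array([cam.width / 2.0, cam.height / 2.0])
    jitter = (rng.normal(0.0, config.jitter_px, size=(n_frames, 2))
              if config.jitter_px > 0 else np.zeros((n_frames, 2)))

    def face_at(f: int) -> np.ndarray:
        return base + jitter[f]

    noise_px = deg_to_px(config.gaze_noise_deg, cam) if config.gaze_noise_deg else 0.0
    dt = 1.0 / config.gaze_hz
    labels = []
    for _ in range(config.n_fixations):
        if rng.random() < config.p_background:
            labels.append("background")
        else:
            labels.append(str(rng.choice(FACE_REGION_NAMES,
                                         p=config.region_probs)))

    gaze: list[GazeSample] = []
    planted: list[PlantedFixation] = []
    t = 0.1
    prev_point = np.array([cam.width / 2.0, cam.height * 0.9])

    def frame_of(tt: float) -> int:
        return min(int(tt * cam.fps), n_frames - 1)

    for k, label in enumerate(labels):
        dur_s = durations_ms[k] / 1000.0
        f_on = frame_of(t)
        target_index = None
        if label == "background":
            for _try in range(100):
                cand = np.array([
                    rng.uniform(0.05 * cam.width, 0.95 * cam.width),
                    rng.uniform(0.05 * cam.height, 0.95 * cam.height),
                ])
                if np.min(np.hypot(*(face_at(f_on) - cand).T)) \
                        > config.background_margin_px:
                    break
            point0 = cand
        else:
            target_index = int(rng.choice(sorted(FACE_REGIONS[label])))
            point0 = face_at(f_on)[target_index].copy()

        n_sac = max(int(config.saccade_ms / 1000.0 / dt), 2)
        for s in range(n_sac):
            frac = (s + 1) / (n_sac + 1)
            ts = t - config.saccade_ms / 1000.0 + s * dt
            if ts < 0:
                continue
            xy = prev_point + frac * (point0 - prev_point)
            gaze.append(_sample(ts, xy, cam, frame_of(ts), rng,
                                config.confidence_range))
        n_dwell = int(dur_s / dt) + 1
        for s in range(n_dwell):
            ts = t + s * dt
            f = frame_of(ts)
            xy = (point0.copy() if label == "background"
                  else face_at(f)[target_index].copy())
            if noise_px:
                xy = xy + rng.normal(0.0, noise_px, size=2)
            gaze.append(_sample(ts, xy, cam, f, rng, config.confidence_range))
        planted.append(PlantedFixation(
            label=label, onset=t, duration_ms=float(durations_ms[k]),
            x_px=float(point0[0]), y_px=float(point0[1]),
            person_index=None if label == "background" else 0,
            landmark_kind=None if label == "background" else "face",
            landmark_index=target_index,
        ))
        prev_point = point0
        t += dur_s + config.saccade_ms / 1000.0

    frames: list[FrameDetections] = []
    visibility: dict[tuple[int, int], str] = {}
    for f in range(n_frames):
        conf = rng.uniform(*config.confidence_range, size=N_FACE_KEYPOINTS)
        pts = face_at(f)
        faces = [FaceDetection(
            [Keypoint(float(x), float(y), float(c))
             for (x, y), c in zip(pts, conf)],
            person_index=0,
        )]
        visibility[(f, 0)] = "full"
        frames.append(FrameDetections(frame_index=f, faces=faces))
    gaze.sort(key=lambda s: s.timestamp)  # guard against float round-off
    return SyntheticScene(
        frames=tuple(frames), gaze=tuple(gaze),
        truth=GroundTruth(fixations=tuple(planted),
                          face_visibility=visibility),
        camera=cam,
    )


def generate_identity_embeddings(
    k: int,
    n_per_identity: int = 50,
    dim: int = 64,
    separation: float = 10.0,
    seed: int = 0,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Surrogate face-recognition embeddings: k unit-variance Gaussian
    blobs whose centroids sit ``separation`` standard deviations apart
    along mutually orthogonal directions.

    Returns (crop_ids, (n, dim) matrix, integer identity labels).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if dim < k:
        raise ValueError("dim must be >= k for orthogonal centroids")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    centers = separation * q[:, :k].T          # pairwise distance sep*sqrt(2)
    labels = np.repeat(np.arange(k), n_per_identity)
    points = centers[labels] + rng.standard_normal((len(labels), dim))
    crop_ids = [f"crop_{i:05d}" for i in range(len(labels))]
    return crop_ids, points, labels


def generate_split_half_participants(
    n: int = 30,
    rho: float = 0.6,
    seed: int = 0,
    mean_logit: float = -1.66,
    sd_logit: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant person-fixation proportions for two route segments
    with a planted population Spearman correlation.

    A bivariate Gaussian latent trait is drawn with the Pearson
    correlation 2*sin(pi*rho/6) that yields Spearman ``rho`` for Gaussian
    pairs, then pushed through a logistic link (Spearman correlation is
    invariant under monotone maps). The default link centers proportions
    near 0.16, the person-fixation rate typical of public-space navigation.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    r = 2.0 * math.sin(math.pi * rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    logits = mean_logit + sd_logit * z
    props = 1.0 / (1.0 + np.exp(-logits))
    return props[:, 0], props[:, 1]


def write_scene(scene: SyntheticScene, directory: str | Path) -> None:
    """Write a scene in the pipeline's on-disk dialects: per-frame keypoint
    JSON under ``detections/``, ``gaze.csv``, and ``truth.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_openpose_dir(scene.frames, directory / "detections")
    write_gaze_csv(scene.gaze, directory / "gaze.csv")
    rows = [{
        "label": p.label,
        "onset": p.onset,
        "duration_ms": p.duration_ms,
        "x_px": p.x_px,
        "y_px": p.y_px,
        "person_index": "" if p.person_index is None else p.person_index,
        "landmark_kind": p.landmark_kind or "",
        "landmark_index": "" if p.landmark_index is None else p.landmark_index,
    } for p in scene.truth.fixations]
    pd.DataFrame(rows).to_csv(directory / "truth.csv", index=False)
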