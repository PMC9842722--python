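"""Dispersion-threshold fixation detection (I-DT) on wearable gaze streams.

A fixation is a maximal run of gaze samples whose angular dispersion — the
maximum pairwise visual-angle separation between samples, measured through
the scene-camera model — stays below a ceiling (default 1.5 degrees), with
a duration between a lower bound (default 80 ms, below which a stable run
is too short to be a fixation) and an upper bound (default 220 ms). Stable
runs longer than the upper bound are split into consecutive fixations so
that total dwell mass is preserved; low-confidence samples (blinks, lost
pupil) are removed first, and a sample gap longer than the minimum duration
closes any open window so a blink can never bridge two fixations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .camera import CameraModel, px_to_deg
from .io_formats import GazeSample

__all__ = ["FixationParams", "FixationRecord", "detect_fixations"]


@dataclass(frozen=True)
class FixationParams:
    """Detector parameters, in visual-angle and time units.

    Defaults are the dispersion/duration settings used with wearable
    trackers: 1.5 degrees maximum dispersion, 80-220 ms duration, and a
    0.6 pupil-confidence floor.
    """

    dispersion_max_deg: float = 1.5
    duration_min_ms: float = 80.0
    duration_max_ms: float = 220.0
    min_confidence: float = 0.6
    max_gap_ms: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.duration_min_ms <= self.duration_max_ms:
            raise ValueError("require 0 < duration_min <= duration_max")
        if self.dispersion_max_deg <= 0:
            raise ValueError("dispersion_max_deg must be positive")
        if self.max_gap_ms <= 0:
            raise ValueError("max_gap_ms must be positive")


@dataclass(frozen=True)
class FixationRecord:
    """A detected fixation with its pixel centroid and frame span."""

    id: int
    start_ts: float          # seconds
    duration_ms: float
    x: float                 # centroid, pixels
    y: float
    dispersion_deg: float
    frame_indices: frozenset[int] = field(default_factory=frozenset)

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


def _pairwise_max_deg(px: np.ndarray, camera: CameraModel) -> float:
    """Max pairwise angular distance of a small set of pixel points."""
    if len(px) < 2:
        return 0.0
    d = px[:, None, :] - px[None, :, :]
    dist = float(np.sqrt((d ** 2).sum(-1)).max())
    return px_to_deg(dist, camera)


def detect_fixations(
    samples: list[GazeSample],
    params: FixationParams | None = None,
    camera: CameraModel | None = None,
) -> list[FixationRecord]:
    """Group gaze samples into fixations with a sliding dispersion window.

    Samples must be time-ordered. Samples with confidence below
    ``params.min_confidence`` are discarded before grouping. The window
    grows while its angular dispersion stays within ``dispersion_max_deg``
    and consecutive samples are closer than ``max_gap_ms`` in time; on
    closing, a window at least ``duration_min_ms`` long is emitted, split
    into equal-duration chunks when it exceeds ``duration_max_ms``.
    Returned fixations are non-overlapping and time-ordered.
    """
    params = params or FixationParams()
    camera = camera or CameraModel()

    ts = np.array([s.timestamp for s in samples], dtype=float)
    if np.any(np.diff(ts) < 0):
        raise ValueError("gaze samples must be time-ordered")

    keep = [s for s in samples if s.confidence >= params.min_confidence]
    n = len(keep)
    if n == 0:
        return []
    t = np.array([s.timestamp for s in keep], dtype=float)
    px = np.array([[s.x, s.y] for s in keep], dtype=float)
    px[:, 0] *= camera.width
    px[:, 1] *= camera.height
    frames = np.array([s.frame_index for s in keep], dtype=int)

    out: list[FixationRecord] = []
    i = 0
    while i < n:
        j = i
        # grow the window sample by sample, tracking the max pairwise
        # pixel distance incrementally (each new sample only adds
        # distances from itself to the existing window)
        max_px_dist = 0.0
        while j + 1 < n:
            if (t[j + 1] - t[j]) * 1000.0 > params.max_gap_ms:
                break
            new_dists = np.sqrt(((px[i:j + 1] - px[j + 1]) ** 2).sum(-1))
            cand = max(max_px_dist, float(new_dists.max()))
            if px_to_deg(cand, camera) > params.dispersion_max_deg:
                break
            max_px_dist = cand
            j += 1
        duration = (t[j] - t[i]) * 1000.0
        if duration >= params.duration_min_ms:
            out.extend(_emit(t, px, frames, i, j, params, camera))
            i = j + 1
        else:
            i += 1

    return [replace(rec, id=k) for k, rec in enumerate(out)]


def _emit(t, px, frames, i, j, params: FixationParams,
          camera: CameraModel) -> list[FixationRecord]:
    """Split window [i..j] into <= duration_max chunks and build records."""
    duration = (t[j] - t[i]) * 1000.0
    n_chunks = max(1, math.ceil(duration / params.duration_max_ms - 1e-9))
    edges = np.linspace(t[i], t[j], n_chunks + 1)
    records: list[FixationRecord] = []
    for c in range(n_chunks):
        lo, hi = edges[c], edges[c + 1]
        if c == 0:
            mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        else:
            mask = (t > edges[c] + 1e-12) & (t <= hi + 1e-12)
        mask &= (np.arange(len(t)) >= i) & (np.arange(len(t)) <= j)
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        chunk_dur = (t[idx[-1]] - t[idx[0]]) * 1000.0
        if n_chunks > 1 and chunk_dur < params.duration_min_ms:
            # custom parameter sets can produce sub-minimum tail chunks
            continue
        centroid = px[idx].mean(axis=0)
        records.append(FixationRecord(
            id=-1,
            start_ts=float(t[idx[0]]),
            duration_ms=float(chunk_dur),
            x=float(centroid[0]),
            y=float(centroid[1]),
            dispersion_deg=_pairwise_max_deg(px[idx], camera),
            frame_indices=frozenset(int(f) for f in frames[idx]),
        ))
    return records
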