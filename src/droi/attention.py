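"""Attention summaries and individual-difference statistics.

All proportions are computed over *fixation-frames*: a fixation spanning k
frames contributes k units. Two denominators are reported:

* ``all_fixation_frames`` — every fixation-frame, so the non-person
  proportion absorbs frames where no person was detectable at all;
* ``detected_frames`` — only fixation-frames in which at least one person
  detection survived confidence filtering, i.e. attention conditional on a
  person being available to look at.

Head proportions count both body-model head landmarks and facial-landmark
registrations (a facial region is part of the head).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .camera import CameraModel
from .detections import FACE_REGION_NAMES, FrameDetections
from .registration import FaceVisibility, FixationAssignment, head_width

__all__ = [
    "AttentionSummary",
    "SplitHalfResult",
    "SizeStratifiedSummary",
    "summarize_attention",
    "stratify_by_face_size",
    "condition_table_full_partial",
    "split_half_correlation",
    "partial_spearman",
]

_HEAD_ROIS = frozenset({"head"}) | frozenset(FACE_REGION_NAMES)


@dataclass(frozen=True)
class AttentionSummary:
    """Head/body/non-person fixation proportions under one denominator."""

    mode: str                     # 'all_fixation_frames' | 'detected_frames'
    p_head: float
    p_body: float
    p_nonperson: float
    n_frames: int                 # denominator size (fixation-frames)
    participant: str | None = None

    def __post_init__(self) -> None:
        total = self.p_head + self.p_body + self.p_nonperson
        if abs(total - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")


@dataclass(frozen=True)
class SplitHalfResult:
    """Spearman split-half reliability with a Fisher-z confidence interval."""

    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class SizeStratifiedSummary:
    """Attention summaries for above- vs below-average face sizes.

    A stratum is ``None`` when it received no fixation-frames (e.g. all
    faces the same size, so nothing is strictly above the mean).
    """

    split_deg: float
    above: AttentionSummary | None
    below: AttentionSummary | None


def _frame_has_detections(frames: Mapping[int, FrameDetections],
                          frame_index: int) -> bool:
    frame = frames.get(frame_index)
    return frame is not None and not frame.is_empty


def summarize_attention(
    assignments: Sequence[FixationAssignment],
    frames: Mapping[int, FrameDetections] | None = None,
    mode: str = "all_fixation_frames",
    participant: str | None = None,
) -> AttentionSummary:
    """Head/body/non-person proportions over fixation-frames.

    ``frames`` must be the confidence-filtered detections and is required
    for ``detected_frames`` mode, where the denominator keeps only
    fixation-frames with at least one surviving person detection.
    """
    if mode == "all_fixation_frames":
        pool = list(assignments)
    elif mode == "detected_frames":
        if frames is None:
            raise ValueError("detected_frames mode requires the frame map")
        pool = [a for a in assignments
                if _frame_has_detections(frames, a.frame_index)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(pool)
    if n == 0:
        raise ValueError(f"no fixation-frames in denominator (mode={mode!r})")
    n_head = sum(a.roi in _HEAD_ROIS for a in pool)
    n_body = sum(a.roi == "body" for a in pool)
    return AttentionSummary(
        mode=mode,
        p_head=n_head / n,
        p_body=n_body / n,
        p_nonperson=(n - n_head - n_body) / n,
        n_frames=n,
        participant=participant,
    )


def _nearest_face_width(assignment: FixationAssignment,
                        frame: FrameDetections,
                        camera: CameraModel) -> float | None:
    """Width of the measurable face nearest the fixation, in degrees."""
    best = None
    for face in frame.faces:
        w = head_width(face, camera)
        if w is None:
            continue
        pts = np.array([[kp.x, kp.y] for kp in face.keypoints if kp.present])
        center = pts.mean(axis=0)
        d = math.hypot(center[0] - assignment.fix_x,
                       center[1] - assignment.fix_y)
        if best is None or d < best[0]:
            best = (d, w)
    return None if best is None else best[1]


def stratify_by_face_size(
    assignments: Sequence[FixationAssignment],
    frames: Mapping[int, FrameDetections],
    camera: CameraModel | None = None,
    mode: str = "detected_frames",
) -> SizeStratifiedSummary:
    """Repeat the attention summary for above- vs below-average face sizes.

    Each fixation-frame is associated with the ear-to-ear width of the
    measurable face nearest the fixation in that frame; frames with no
    measurable face are left out of both strata. The split point is the
    mean width over the associated faces; 'above' is strictly above.
    """
    camera = camera or CameraModel()
    widths: list[float | None] = []
    for a in assignments:
        frame = frames.get(a.frame_index)
        widths.append(None if frame is None
                      else _nearest_face_width(a, frame, camera))
    measured = [w for w in widths if w is not None]
    if not measured:
        raise ValueError("no measurable faces for size stratification")
    split = float(np.mean(measured))

    def _maybe(pool):
        if not pool:
            return None
        return summarize_attention(pool, frames, mode)

    # strictly-above split, with a tolerance so that identical widths never
    # land above their own mean through summation rounding
    tol = 1e-9 * max(split, 1.0)
    above = [a for a, w in zip(assignments, widths)
             if w is not None and w > split + tol]
    below = [a for a, w in zip(assignments, widths)
             if w is not None and w <= split + tol]
    return SizeStratifiedSummary(split_deg=split,
                                 above=_maybe(above), below=_maybe(below))


def condition_table_full_partial(
    assignments: Sequence[FixationAssignment],
    visibilities: Sequence[FaceVisibility],
) -> dict[str, dict[str, float] | None]:
    """Head/body proportions conditioned on face visibility (full/partial).

    Each fixation-frame is labelled with the visibility status of the
    assigned person's face, or — for frames not registered to a person —
    of any face in the frame (nearest by person index); fixation-frames
    with no face visibility information are excluded. Within each
    condition, proportions are over that condition's fixation-frames. A
    condition with no frames maps to ``None``.
    """
    vis: dict[tuple[int, int], str] = {
        (v.frame_index, v.person_index): v.status for v in visibilities
    }
    by_frame: dict[int, list[str]] = {}
    for (fi, _pid), status in sorted(vis.items()):
        by_frame.setdefault(fi, []).append(status)

    pools: dict[str, list[FixationAssignment]] = {"full": [], "partial": []}
    for a in assignments:
        if a.is_person and (a.frame_index, a.person_index) in vis:
            status = vis[(a.frame_index, a.person_index)]
        elif a.frame_index in by_frame:
            status = by_frame[a.frame_index][0]
        else:
            continue
        pools[status].append(a)

    table: dict[str, dict[str, float] | None] = {}
    for condition, pool in pools.items():
        if not pool:
            table[condition] = None
            continue
        n = len(pool)
        table[condition] = {
            "p_head": sum(a.roi in _HEAD_ROIS for a in pool) / n,
            "p_body": sum(a.roi == "body" for a in pool) / n,
            "n_frames": n,
        }
    return table


def split_half_correlation(x: Sequence[float], y: Sequence[float],
                           alpha: float = 0.05) -> SplitHalfResult:
    """Spearman rank correlation between two session segments.

    The confidence interval uses the Fisher z transform with the
    rank-correlation variance correction 1.06/(n-3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    if n > 3 and abs(rho) < 1.0:
        z = np.arctanh(rho)
        se = math.sqrt(1.06 / (n - 3))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    else:
        lo, hi = (rho, rho)
    return SplitHalfResult(rho=float(rho), p_value=float(p),
                           ci_low=float(lo), ci_high=float(hi), n=n)


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     covariate: Sequence[float]) -> float:
    """Spearman correlation of x and y partialling out one covariate.

    Computed with the first-order partial-correlation formula on the three
    pairwise Spearman correlations, equivalent to correlating the
    residuals of rank-regressions on the ranked covariate.
    """
    arrs = [np.asarray(v, dtype=float) for v in (x, y, covariate)]
    n = len(arrs[0])
    if any(a.shape != (n,) for a in arrs):
        raise ValueError("x, y and covariate must be paired 1-d vectors")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if any(np.ptp(a) == 0 for a in arrs):
        raise ValueError("rank correlation undefined for a constant vector")
    r_xy = stats.spearmanr(arrs[0], arrs[1]).statistic
    r_xz = stats.spearmanr(arrs[0], arrs[2]).statistic
    r_yz = stats.spearmanr(arrs[1], arrs[2]).statistic
    denom = math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    num = r_xy - r_xz * r_yz
    if denom < 1e-12:
        # covariate rank-identical to x or y: nothing left to correlate
        if abs(num) < 1e-9:
            return 0.0
        raise ValueError("covariate fully explains x or y; partial rho undefined")
    return float(num / denom)
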