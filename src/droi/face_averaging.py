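"""Face-diet machinery: identity clustering, fixated/non-fixated splits and
morph-based average faces.

Face crops (full 70-landmark detections only) are grouped into identities
by K-means on face-embedding vectors, with the cluster count chosen by the
elbow of the within-cluster sum-of-squares curve. Crops are split into
fixated and non-fixated instances using the registration output, and each
set is collapsed into a morph average: every crop is piecewise-affine
warped to the canonical template, pixels are averaged first within and then
across identities — so each identity contributes equally regardless of how
often it was seen — and the result is warped to the equally-weighted mean
landmark geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from ._geometry import GeometryError, barycentric, bilinear_sample
from .detections import N_FACE_KEYPOINTS
from .face_template import FaceTemplate
from .registration import FixationAssignment

__all__ = [
    "FaceCrop",
    "IdentityCluster",
    "ElbowResult",
    "AverageFace",
    "cluster_identities",
    "select_k_elbow",
    "split_fixated_nonfixated",
    "warp_to_landmarks",
    "average_faces",
]


@dataclass
class FaceCrop:
    """One cropped face image with its 70 landmarks in crop coordinates."""

    crop_id: str
    image: np.ndarray                  # (H, W) or (H, W, 3) float in [0, 1]
    landmarks: np.ndarray              # (70, 2)
    frame_index: int = -1
    person_index: int = 0
    fixated: bool | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (N_FACE_KEYPOINTS, 2):
            raise ValueError(f"landmarks must be ({N_FACE_KEYPOINTS}, 2)")


@dataclass(frozen=True)
class IdentityCluster:
    identity_id: int
    member_crop_ids: tuple
    centroid: np.ndarray


@dataclass(frozen=True)
class ElbowResult:
    """Within-cluster sum-of-squares curve and the selected cluster count."""

    ks: tuple[int, ...]
    wcss: tuple[float, ...]
    selected_k: int


def select_k_elbow(ks: Sequence[int], wcss: Sequence[float],
                   min_improvement: float = 0.1) -> int:
    """Pick the elbow of a WCSS curve.

    Both axes are normalized to [0, 1] and the point with maximum
    perpendicular distance to the chord joining the curve's endpoints is
    selected. A curve with no pronounced elbow — no single step shrinking
    the WCSS by at least ``min_improvement`` (relative) — selects the
    smallest k: splitting an unclustered point cloud only ever shaves a few
    percent per step, whereas reaching a true cluster count removes the
    between-cluster sum of squares in one step.
    """
    ks = np.asarray(ks, dtype=float)
    wc = np.asarray(wcss, dtype=float)
    if len(ks) != len(wc) or len(ks) == 0:
        raise ValueError("ks and wcss must be non-empty and paired")
    if len(ks) < 3 or np.ptp(wc) < 1e-12:
        return int(ks[0]) if np.ptp(wc) < 1e-12 else int(ks[np.argmin(wc)])
    with np.errstate(divide="ignore", invalid="ignore"):
        steps = np.where(wc[:-1] > 0, 1.0 - wc[1:] / wc[:-1], 0.0)
    if np.nanmax(steps) < min_improvement:
        return int(ks[0])
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (wc - wc.min()) / np.ptp(wc)
    # distance from (x, y) to the chord through (x0,y0)-(x1,y1)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist /= np.hypot(y1 - y0, x1 - x0)
    return int(ks[int(np.argmax(dist))])


def cluster_identities(
    crop_ids: Sequence,
    embeddings: np.ndarray,
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 5,
) -> tuple[list[IdentityCluster], ElbowResult]:
    """Estimate face identities by K-means plus the elbow method.

    K-means is fitted for k = 1..k_max (``n_restarts`` restarts each, seeded)
    and the cluster count is chosen by :func:`select_k_elbow` on the WCSS
    curve. Returns the clusters at the selected k together with the elbow
    diagnostics.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    x = np.asarray(embeddings, dtype=float)
    if x.ndim != 2 or len(crop_ids) != x.shape[0]:
        raise ValueError("embeddings must be (n_crops, dim)")
    if not np.all(np.isfinite(x)):
        raise ValueError("embeddings must be finite")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 crops to cluster")
    if k_max > n:
        warnings.warn(f"k_max={k_max} exceeds the number of crops; clamping")
        k_max = n

    ks = list(range(1, k_max + 1))
    wcss: list[float] = []
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        with warnings.catch_warnings():
            # duplicate points legitimately yield fewer distinct clusters
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            km.fit(x)
        fits[k] = km
        wcss.append(float(km.inertia_))
    k_sel = select_k_elbow(ks, wcss)
    km = fits[k_sel]
    clusters = []
    for cid in range(k_sel):
        members = tuple(crop_ids[i] for i in np.nonzero(km.labels_ == cid)[0])
        if not members:
            continue
        clusters.append(IdentityCluster(
            identity_id=cid, member_crop_ids=members,
            centroid=km.cluster_centers_[cid].copy(),
        ))
    elbow = ElbowResult(ks=tuple(ks), wcss=tuple(wcss), selected_k=k_sel)
    return clusters, elbow


def split_fixated_nonfixated(
    crops: Sequence[FaceCrop],
    assignments: Sequence[FixationAssignment],
) -> tuple[list[FaceCrop], list[FaceCrop]]:
    """Partition crops by whether their face was fixated in their frame.

    A crop is fixated iff some person-registered assignment in the crop's
    frame points at the crop's person. Returns (fixated, non_fixated).
    """
    hit = {(a.frame_index, a.person_index)
           for a in assignments if a.is_person}
    fixated, non_fixated = [], []
    for crop in crops:
        if (crop.frame_index, crop.person_index) in hit:
            fixated.append(crop)
        else:
            non_fixated.append(crop)
    return fixated, non_fixated


def warp_to_landmarks(
    image: np.ndarray,
    src_landmarks: np.ndarray,
    dst_landmarks: np.ndarray,
    triangles: np.ndarray,
    output_shape: tuple[int, int] | None = None,
    fill: float = 0.5,
) -> np.ndarray:
    """Piecewise-affine warp of ``image`` from one landmark geometry to
    another over a shared triangulation.

    For every triangle, output pixels inside the destination triangle are
    pulled from the source image through the affine map defined by the
    three vertex correspondences (implemented via barycentric coordinates,
    which the affine map preserves), with bilinear sampling. Pixels outside
    the destination hull are filled with ``fill`` (mid-grey by default).
    """
    image = np.asarray(image, dtype=float)
    src = np.asarray(src_landmarks, dtype=float)
    dst = np.asarray(dst_landmarks, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("landmark sets must both be (n, 2)")
    if output_shape is None:
        h = int(np.ceil(dst[:, 1].max())) + 1
        w = int(np.ceil(dst[:, 0].max())) + 1
    else:
        h, w = output_shape
    out_shape = (h, w) if image.ndim == 2 else (h, w, image.shape[2])
    out = np.full(out_shape, fill, dtype=float)

    for ti, tri in enumerate(triangles):
        d_tri = dst[tri]
        s_tri = src[tri]
        x0 = max(int(np.floor(d_tri[:, 0].min())), 0)
        x1 = min(int(np.ceil(d_tri[:, 0].max())) + 1, w)
        y0 = max(int(np.floor(d_tri[:, 1].min())), 0)
        y1 = min(int(np.ceil(d_tri[:, 1].max())) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1, dtype=float),
                             np.arange(y0, y1, dtype=float))
        pts = np.column_stack((xs.ravel(), ys.ravel()))
        try:
            wts = barycentric(pts, d_tri)
        except GeometryError as exc:
            raise GeometryError(
                f"degenerate destination triangle {ti} "
                f"(vertices {tuple(int(v) for v in tri)})") from exc
        inside = np.all(wts >= -1e-9, axis=1)
        if not inside.any():
            continue
        # affine source positions via the shared barycentric weights
        src_pts = wts[inside] @ s_tri
        vals = bilinear_sample(image, src_pts[:, 0], src_pts[:, 1])
        yy = ys.ravel()[inside].astype(int)
        xx = xs.ravel()[inside].astype(int)
        out[yy, xx] = vals
    return out


@dataclass(frozen=True)
class AverageFace:
    """A morph average over identities, with equal identity contribution."""

    image: np.ndarray
    mean_landmarks: np.ndarray
    n_identities: int
    condition: str | None = None      # 'fixated' | 'non_fixated'


def average_faces(
    crops_by_identity: Mapping[int, Sequence[FaceCrop]],
    template: FaceTemplate,
    condition: str | None = None,
    output_shape: tuple[int, int] | None = None,
    fill: float = 0.5,
) -> AverageFace:
    """Build a morph-average face with equal per-identity contribution.

    Every crop is warped to the template geometry; pixel means are taken
    first within each identity and then across identity means, so the
    result is invariant to how many crops an identity contributed. Mean
    landmarks are computed with the same two-level weighting, and the
    grand-mean image is finally warped from the template to those mean
    landmarks.
    """
    if not crops_by_identity or any(len(v) == 0
                                    for v in crops_by_identity.values()):
        raise ValueError("every identity must contribute at least one crop")
    if output_shape is None:
        b = template.bounds
        output_shape = (int(np.ceil(b[3])) + 1, int(np.ceil(b[2])) + 1)

    identity_means = []
    identity_landmarks = []
    for _identity, crops in sorted(crops_by_identity.items()):
        warped = [
            warp_to_landmarks(c.image, c.landmarks, template.landmarks,
                              template.triangles, output_shape=output_shape,
                              fill=fill)
            for c in crops
        ]
        identity_means.append(np.mean(warped, axis=0))
        identity_landmarks.append(
            np.mean([c.landmarks for c in crops], axis=0))
    grand_mean = np.mean(identity_means, axis=0)
    mean_landmarks = np.mean(identity_landmarks, axis=0)

    final = warp_to_landmarks(grand_mean, template.landmarks, mean_landmarks,
                              template.triangles, output_shape=output_shape,
                              fill=fill)
    return AverageFace(image=final, mean_landmarks=mean_landmarks,
                       n_identities=len(crops_by_identity),
                       condition=condition)
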