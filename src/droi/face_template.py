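"""Canonical face template: triangulated projection, heatmaps, heatmap PCA.

Fixations on a detected face are carried into a common coordinate system by
(1) triangulating the 70 template landmarks once (Delaunay), (2)
transferring that triangulation to the frame's detected landmarks by vertex
correspondence, (3) locating the triangle containing the fixation and
expressing it in barycentric coordinates, and (4) re-evaluating those
coordinates on the template triangle — the per-triangle affine map.
Because affine maps preserve barycentric coordinates, template positions
are exactly invariant to affine distortions of the detected face.

The canonical 70-point geometry shipped here is a synthetic, bilaterally
symmetric frontal face constructed from parametric curves (jaw ellipse,
brow arcs, nose axis, eye rings, lip ellipses, pupils), laid out in a
nominal 200 x 200 unit box. It is a documented default, replaceable by any
70-point geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._geometry import GeometryError, locate_triangle, triangle_areas
from .detections import FACE_REGION_NAMES, N_FACE_KEYPOINTS
from .registration import FixationAssignment

__all__ = [
    "FaceTemplate",
    "TemplateFixation",
    "Heatmap",
    "HeatmapPCA",
    "OutsideFaceError",
    "default_template_landmarks",
    "default_face_template",
    "build_triangulation",
    "project_to_template",
    "build_heatmap",
    "region_proportions",
    "heatmap_pca",
]


class OutsideFaceError(GeometryError):
    """The point lies outside the convex hull of the detected landmarks."""


def build_triangulation(landmarks: np.ndarray) -> np.ndarray:
    """Delaunay triangulation of a landmark set, deterministically ordered.

    Each triangle's vertex indices are sorted ascending and the triangle
    list is sorted lexicographically, so the same landmark geometry always
    yields the same triangle ordering.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.ndim != 2 or landmarks.shape[1] != 2 or len(landmarks) < 3:
        raise GeometryError("need at least 3 two-dimensional points")
    if len(np.unique(landmarks, axis=0)) != len(landmarks):
        raise GeometryError("duplicate landmark positions")
    try:
        tri = Delaunay(landmarks)
    except QhullError as exc:
        raise GeometryError(f"triangulation failed: {exc}") from exc
    simplices = np.sort(tri.simplices, axis=1)
    order = np.lexsort((simplices[:, 2], simplices[:, 1], simplices[:, 0]))
    simplices = simplices[order]
    if np.any(triangle_areas(landmarks, simplices) <= 0):
        raise GeometryError("triangulation contains a zero-area triangle")
    return simplices


def default_template_landmarks() -> np.ndarray:
    """The shipped canonical 70-point frontal face geometry.

    Landmark indices follow the standard layout: jaw 0-16, brows 17-26,
    nose 27-35, eyes 36-47, lips 48-67, pupils 68-69. Coordinates are in
    template units with origin top-left, x right, y down; the face is
    exactly symmetric about x = 100.
    """
    pts = np.zeros((N_FACE_KEYPOINTS, 2))
    # jaw contour 0..16: half-ellipse from the left ear down under the chin
    # and back up to the right ear
    t = np.linspace(0.0, np.pi, 17)
    pts[0:17, 0] = 100.0 - 80.0 * np.cos(t)
    pts[0:17, 1] = 88.0 + 96.0 * np.sin(t)
    # brows 17-21 (image-left) and 22-26 (image-right): shallow arcs
    bx = np.linspace(-62.0, -14.0, 5)
    by = 62.0 - 6.0 * np.cos(np.linspace(-1.0, 1.0, 5))
    pts[17:22] = np.column_stack((100.0 + bx, by))
    pts[22:27] = np.column_stack((100.0 - bx[::-1], by[::-1]))
    # nose bridge 27-30 and nostril line 31-35
    pts[27:31] = np.column_stack((np.full(4, 100.0),
                                  np.linspace(78.0, 116.0, 4)))
    pts[31:36] = np.column_stack((np.linspace(86.0, 114.0, 5),
                                  [126.0, 129.0, 130.0, 129.0, 126.0]))
    # eye rings: 6 points each, angles chosen to give the standard order
    # (outer corner, two upper-lid, inner corner, two lower-lid points)
    ang = np.array([180.0, 135.0, 45.0, 0.0, 315.0, 225.0]) * np.pi / 180.0
    ex, ey = 16.0 * np.cos(ang), -7.0 * np.sin(ang)
    pts[36:42] = np.column_stack((62.0 + ex, 82.0 + ey))
    pts[42:48] = np.column_stack((138.0 - ex, 82.0 + ey))
    # outer lips 48-59 (12 points) and inner lips 60-67 (8 points)
    ang12 = np.pi * (1.0 - np.arange(12) / 6.0)
    pts[48:60] = np.column_stack((100.0 + 27.0 * np.cos(ang12),
                                  152.0 - 13.0 * np.sin(ang12)))
    ang8 = np.pi * (1.0 - np.arange(8) / 4.0)
    pts[60:68] = np.column_stack((100.0 + 17.0 * np.cos(ang8),
                                  152.0 - 6.0 * np.sin(ang8)))
    # pupils
    pts[68] = (62.0, 82.0)
    pts[69] = (138.0, 82.0)
    return pts


@dataclass(frozen=True)
class FaceTemplate:
    """Canonical 70-landmark geometry plus its Delaunay triangulation."""

    landmarks: np.ndarray
    triangles: np.ndarray

    @classmethod
    def from_landmarks(cls, landmarks: np.ndarray) -> "FaceTemplate":
        landmarks = np.asarray(landmarks, dtype=float)
        return cls(landmarks=landmarks,
                   triangles=build_triangulation(landmarks))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the landmark set."""
        lo = self.landmarks.min(axis=0)
        hi = self.landmarks.max(axis=0)
        return float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1])

    @property
    def width(self) -> float:
        b = self.bounds
        return b[2] - b[0]

    @property
    def height(self) -> float:
        b = self.bounds
        return b[3] - b[1]


def default_face_template() -> FaceTemplate:
    return FaceTemplate.from_landmarks(default_template_landmarks())


@dataclass(frozen=True)
class TemplateFixation:
    """A fixation carried into template coordinates."""

    fixation_id: int
    x: float                  # template units
    y: float
    triangle_id: int
    weights: tuple[float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("barycentric weights must be a convex combination")


def project_to_template(point, detected_landmarks: np.ndarray,
                        template: FaceTemplate,
                        fixation_id: int = -1) -> TemplateFixation:
    """Map a pixel point on a detected face into template coordinates.

    ``detected_landmarks`` must be the full (70, 2) set (full faces only).
    The template triangulation is transferred to the detected landmarks by
    vertex correspondence; the containing triangle's barycentric weights
    are re-evaluated on the template triangle. Raises
    :class:`OutsideFaceError` when the point lies outside every detected
    triangle.
    """
    detected = np.asarray(detected_landmarks, dtype=float)
    if detected.shape != template.landmarks.shape:
        raise ValueError(
            f"detected landmarks must be shaped {template.landmarks.shape}")
    hit = locate_triangle(point, detected, template.triangles)
    if hit is None:
        raise OutsideFaceError(
            f"point {tuple(np.asarray(point, float))} is outside the "
            "detected-face triangulation")
    ti, w = hit
    tpl_tri = template.landmarks[template.triangles[ti]]
    xy = w @ tpl_tri
    return TemplateFixation(fixation_id=fixation_id, x=float(xy[0]),
                            y=float(xy[1]), triangle_id=int(ti),
                            weights=tuple(float(v) for v in w))


@dataclass(frozen=True)
class Heatmap:
    """A unit-mass fixation density on a regular template-space grid."""

    grid: np.ndarray              # (H, W), non-negative
    bandwidth: float              # template units
    n_fixations: int
    extent: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max

    def mirrored(self) -> np.ndarray:
        """Grid mirrored about the vertical midline (for symmetry checks)."""
        return self.grid[:, ::-1]


def build_heatmap(points: Sequence[TemplateFixation] | np.ndarray,
                  template: FaceTemplate,
                  bandwidth: float | None = None,
                  grid_shape: tuple[int, int] = (64, 64)) -> Heatmap:
    """Aggregate template-space fixations into a Gaussian-kernel heatmap.

    An isotropic Gaussian of standard deviation ``bandwidth`` (default 2%
    of the template width) is deposited at each fixation, evaluated at grid
    cell centers over the template bounding box, and the grid is normalized
    to total mass 1. Zero points yield an all-zero grid with
    ``n_fixations = 0``.
    """
    if bandwidth is None:
        bandwidth = 0.02 * template.width
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    h, w = grid_shape
    x_min, y_min, x_max, y_max = template.bounds
    if isinstance(points, np.ndarray):
        pts = np.atleast_2d(points).astype(float)
    else:
        pts = np.array([[p.x, p.y] for p in points], dtype=float)
    extent = (x_min, y_min, x_max, y_max)
    if pts.size == 0:
        return Heatmap(grid=np.zeros((h, w)), bandwidth=float(bandwidth),
                       n_fixations=0, extent=extent)
    xc = x_min + (np.arange(w) + 0.5) * (x_max - x_min) / w
    yc = y_min + (np.arange(h) + 0.5) * (y_max - y_min) / h
    dx = xc[None, :] - pts[:, 0, None]          # (n, W)
    dy = yc[None, :] - pts[:, 1, None]          # (n, H)
    gx = np.exp(-0.5 * (dx / bandwidth) ** 2)
    gy = np.exp(-0.5 * (dy / bandwidth) ** 2)
    grid = gy.T @ gx                             # (H, W)
    grid /= grid.sum()
    return Heatmap(grid=grid, bandwidth=float(bandwidth),
                   n_fixations=len(pts), extent=extent)


def region_proportions(
    assignments: Sequence[FixationAssignment],
) -> dict[str, float]:
    """Proportion of face-registered fixation-frames per facial region.

    Only assignments labelled with one of the five facial regions count;
    proportions sum to 1 over the five categories.
    """
    counts = {name: 0 for name in FACE_REGION_NAMES}
    for a in assignments:
        if a.roi in counts:
            counts[a.roi] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no facial-region fixation-frames")
    return {name: counts[name] / total for name in FACE_REGION_NAMES}


@dataclass(frozen=True)
class HeatmapPCA:
    """Principal components of inter-individual heatmap variation."""

    components: np.ndarray            # (k, H, W)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray                # (n_participants, k)
    mean: np.ndarray                  # (H, W)

    def reconstruct(self) -> np.ndarray:
        """Reconstruct all participant heatmaps from all components."""
        flat = self.scores @ self.components.reshape(len(self.components), -1)
        return flat.reshape((-1,) + self.mean.shape) + self.mean


def heatmap_pca(heatmaps: Sequence[Heatmap | np.ndarray]) -> HeatmapPCA:
    """PCA over participants' heatmaps, components ranked by explained
    variance. Grids are flattened, centered across participants and
    decomposed with a full SVD; identical heatmaps (zero variance) yield
    zero components."""
    grids = [hm.grid if isinstance(hm, Heatmap) else np.asarray(hm, float)
             for hm in heatmaps]
    if len(grids) < 2:
        raise ValueError("need at least 2 heatmaps")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("heatmaps must share grid dimensions")
    x = np.stack([g.ravel() for g in grids])
    mean = x.mean(axis=0)
    xc = x - mean
    if float(np.abs(xc).max()) < 1e-15:
        k = 0
        return HeatmapPCA(
            components=np.zeros((0,) + shape),
            explained_variance_ratio=np.zeros(0),
            scores=np.zeros((len(grids), 0)),
            mean=mean.reshape(shape),
        )
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    keep = var > var[0] * 1e-24
    u, s, vt, var = u[:, keep], s[keep], vt[keep], var[keep]
    return HeatmapPCA(
        components=vt.reshape((-1,) + shape),
        explained_variance_ratio=var / var.sum(),
        scores=u * s,
        mean=mean.reshape(shape),
    )
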