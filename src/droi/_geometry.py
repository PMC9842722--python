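"""Shared triangle geometry: barycentric coordinates, point location,
bilinear sampling. Used by the template projection and image morphing code."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "GeometryError",
    "triangle_areas",
    "barycentric",
    "locate_triangle",
    "bilinear_sample",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry (collinear points, zero-area
    triangles, points outside a triangulation)."""


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Unsigned areas of ``triangles`` (index triplets into ``vertices``)."""
    a, b, c = (vertices[triangles[:, i]] for i in range(3))
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) \
        - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    return np.abs(cross) / 2.0


def barycentric(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``points`` (m, 2) w.r.t. triangle ``tri``
    (3, 2). Raises :class:`GeometryError` for a degenerate triangle."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a, b, c = np.asarray(tri, dtype=float)
    m = np.column_stack((b - a, c - a))  # 2x2
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) < 1e-12:
        raise GeometryError("degenerate (zero-area) triangle")
    inv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
    uv = (points - a) @ inv.T
    w0 = 1.0 - uv[:, 0] - uv[:, 1]
    return np.column_stack((w0, uv))


def locate_triangle(point, vertices: np.ndarray, triangles: np.ndarray,
                    tol: float = 1e-9):
    """Find the first triangle containing ``point``.

    Returns ``(triangle_id, weights)`` with all weights >= -tol, or
    ``None`` if the point is outside every triangle. Triangle order is the
    deterministic order of ``triangles``, so points on shared edges resolve
    to the lowest triangle id.
    """
    point = np.asarray(point, dtype=float)
    for ti, tri in enumerate(triangles):
        w = barycentric(point, vertices[tri])[0]
        if np.all(w >= -tol):
            return ti, np.clip(w, 0.0, None) / np.clip(w, 0.0, None).sum()
    return None


def bilinear_sample(image: np.ndarray, xs: np.ndarray, ys: np.ndarray
                    ) -> np.ndarray:
    """Sample ``image`` at continuous (x, y) positions with bilinear
    interpolation; out-of-bounds positions clamp to the edge. Supports
    single-channel (H, W) and multi-channel (H, W, C) images."""
    if image.ndim == 2:
        return map_coordinates(image.astype(float), [ys, xs], order=1,
                               mode="nearest")
    return np.stack([
        map_coordinates(image[..., c].astype(float), [ys, xs], order=1,
                        mode="nearest")
        for c in range(image.shape[2])
    ], axis=-1)
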