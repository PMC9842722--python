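"""Scene-camera model and pixel/visual-angle conversions.

All pixel coordinates in this package use the image convention: origin at
the top-left corner, x increasing rightwards, y increasing downwards,
0-based continuous coordinates. Sizes and gaze dispersion are expressed in
degrees of visual angle, the hardware-independent unit, via a pinhole
camera model with a configurable horizontal field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CameraModel", "px_to_deg", "deg_to_px"]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole model of the forward-facing scene camera.

    Parameters
    ----------
    width, height : int
        Frame resolution in pixels. The default 1920x1080 matches common
        wearable scene cameras.
    horizontal_fov : float
        Horizontal field of view in degrees, the single intrinsic this
        package needs. The 90 degree default is a placeholder and should be
        overridden with the real optics when absolute visual angles matter.
    fps : float
        Scene-camera frame rate in frames per second.
    """

    width: int = 1920
    height: int = 1080
    horizontal_fov: float = 90.0
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("camera resolution must be positive")
        if not 0.0 < self.horizontal_fov < 180.0:
            raise ValueError("horizontal_fov must lie in (0, 180) degrees")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def norm_to_px(self, x: float, y: float) -> tuple[float, float]:
        """Map top-left-origin normalized coordinates to pixels."""
        return x * self.width, y * self.height

    def px_to_norm(self, x: float, y: float) -> tuple[float, float]:
        return x / self.width, y / self.height


def px_to_deg(distance, camera: CameraModel):
    """Convert an on-image segment length in pixels to degrees of visual angle.

    Uses the pinhole small-segment relation for a segment centered on the
    optical axis::

        deg = 2 * atan( (distance / width) * tan(fov / 2) )

    Accepts scalars or arrays; distances must be non-negative.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("pixel distance must be non-negative")
    half_fov = math.radians(camera.horizontal_fov) / 2.0
    out = np.degrees(2.0 * np.arctan((d / camera.width) * math.tan(half_fov)))
    return float(out) if np.isscalar(distance) or out.ndim == 0 else out


def deg_to_px(angle, camera: CameraModel):
    """Inverse of :func:`px_to_deg` (degrees of visual angle to pixels)."""
    a = np.asarray(angle, dtype=float)
    if np.any(a < 0):
        raise ValueError("angle must be non-negative")
    if np.any(a >= 180.0):
        raise ValueError("angle must be below 180 degrees")
    half_fov = math.radians(camera.horizontal_fov) / 2.0
    out = camera.width * np.tan(np.radians(a) / 2.0) / math.tan(half_fov)
    return float(out) if np.isscalar(angle) or out.ndim == 0 else out
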