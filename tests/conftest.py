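import numpy as np
import pytest

import droi


@pytest.fixture(scope="session")
def camera():
    return droi.CameraModel()  # 1920x1080, 90 deg fov, 60 fps


@pytest.fixture(scope="session")
def template():
    return droi.default_face_template()


@pytest.fixture(scope="session")
def nav_scene():
    """Small noisy navigation scene shared by read-only tests."""
    return droi.generate_navigation_scene(droi.SceneConfig(
        n_fixations=60, p_head=0.3, p_body=0.3, p_background=0.4, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_body(points, confidences=None, person_index=0):
    """Build a BodyDetection from a (25, 2) array; None rows are missing."""
    kps = []
    for i, pt in enumerate(points):
        if pt is None:
            kps.append(droi.Keypoint.missing())
        else:
            c = 0.9 if confidences is None else confidences[i]
            kps.append(droi.Keypoint(float(pt[0]), float(pt[1]), float(c)))
    return droi.BodyDetection(kps, person_index=person_index)


def make_face(points, confidences=None, person_index=0):
    kps = []
    for i, pt in enumerate(points):
        if pt is None:
            kps.append(droi.Keypoint.missing())
        else:
            c = 0.9 if confidences is None else confidences[i]
            kps.append(droi.Keypoint(float(pt[0]), float(pt[1]), float(c)))
    return droi.FaceDetection(kps, person_index=person_index)
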