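import numpy as np
import pytest

import droi
from droi._geometry import GeometryError


def _smooth_image(shape, rng=None):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = 0.5 + 0.25 * np.sin(xx / 17.0) * np.cos(yy / 13.0)
    if rng is not None:
        img = np.clip(img + 0.02 * rng.standard_normal(shape), 0, 1)
    return img


def _hull_mask(shape, landmarks, erode=2.0):
    """Boolean mask of pixels safely inside the landmark convex hull."""
    from scipy.spatial import Delaunay

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    hull = Delaunay(landmarks)
    inside = hull.find_simplex(pts) >= 0
    # also require the eroded position to stay inside
    c = landmarks.mean(axis=0)
    shrunk = c + (pts - c) * (1 + erode / 100.0)
    inside &= hull.find_simplex(shrunk) >= 0
    return inside.reshape(shape)


class TestSelectKElbow:
    def test_sharp_elbow(self):
        wcss = [100.0, 40.0, 8.0, 7.0, 6.5, 6.2]
        assert droi.select_k_elbow(range(1, 7), wcss) == 3

    def test_flat_curve_selects_one(self):
        assert droi.select_k_elbow([1, 2, 3], [5.0, 5.0, 5.0]) == 1


class TestClusterIdentities:
    def test_identical_embeddings_give_single_cluster(self):
        ids = [f"c{i}" for i in range(10)]
        emb = np.ones((10, 4))
        clusters, elbow = droi.cluster_identities(ids, emb, k_max=5)
        assert elbow.selected_k == 1
        assert len(clusters) == 1
        assert set(clusters[0].member_crop_ids) == set(ids)

    def test_three_blobs_recovered_with_nearest_centroid_membership(self):
        ids, emb, labels = droi.generate_identity_embeddings(
            3, n_per_identity=50, separation=10.0, seed=2)
        clusters, elbow = droi.cluster_identities(ids, emb, k_max=8, seed=0)
        assert elbow.selected_k == 3
        # membership equals nearest-true-centroid assignment
        true_centroids = np.stack([emb[labels == k].mean(axis=0)
                                   for k in range(3)])
        id_to_row = {cid: i for i, cid in enumerate(ids)}
        for cluster in clusters:
            rows = [id_to_row[c] for c in cluster.member_crop_ids]
            nearest = np.linalg.norm(
                emb[rows][:, None, :] - true_centroids[None], axis=2
            ).argmin(axis=1)
            assert len(set(nearest)) == 1
            assert len({labels[r] for r in rows}) == 1

    def test_wcss_matches_recount_from_memberships(self):
        ids, emb, _ = droi.generate_identity_embeddings(3, 30, seed=4)
        clusters, elbow = droi.cluster_identities(ids, emb, k_max=6, seed=0)
        id_to_row = {cid: i for i, cid in enumerate(ids)}
        recount = 0.0
        for c in clusters:
            rows = [id_to_row[m] for m in c.member_crop_ids]
            mu = emb[rows].mean(axis=0)
            recount += ((emb[rows] - mu) ** 2).sum()
        assert recount == pytest.approx(elbow.wcss[elbow.selected_k - 1],
                                        rel=1e-9)

    def test_deterministic_under_fixed_seed(self):
        ids, emb, _ = droi.generate_identity_embeddings(4, 20, seed=6)
        a = droi.cluster_identities(ids, emb, k_max=6, seed=3)
        b = droi.cluster_identities(ids, emb, k_max=6, seed=3)
        assert a[1] == b[1]
        assert [c.member_crop_ids for c in a[0]] == \
            [c.member_crop_ids for c in b[0]]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            droi.cluster_identities(["a", "b"], np.zeros((2, 3)), k_max=0)
        with pytest.raises(ValueError):
            droi.cluster_identities(["a"], np.zeros((1, 3)))
        with pytest.warns(UserWarning, match="clamping"):
            droi.cluster_identities(
                ["a", "b", "c"], np.arange(6).reshape(3, 2) * 1.0, k_max=9)


class TestSplitFixatedNonFixated:
    def _crop(self, frame, person, template):
        return droi.FaceCrop(crop_id=f"f{frame}p{person}",
                             image=np.zeros((8, 8)),
                             landmarks=template.landmarks,
                             frame_index=frame, person_index=person)

    def _hit(self, frame, person):
        return droi.FixationAssignment(
            fixation_id=0, frame_index=frame, roi="head",
            person_index=person, landmark_kind="body", landmark_index=0,
            distance_px=1.0)

    def test_no_assignments_all_non_fixated(self, template):
        crops = [self._crop(i, 0, template) for i in range(4)]
        fixated, non_fixated = droi.split_fixated_nonfixated(crops, [])
        assert fixated == [] and non_fixated == crops

    def test_every_frame_fixated(self, template):
        crops = [self._crop(i, 0, template) for i in range(4)]
        asg = [self._hit(i, 0) for i in range(4)]
        fixated, non_fixated = droi.split_fixated_nonfixated(crops, asg)
        assert fixated == crops and non_fixated == []

    def test_partition_matches_planted_truth(self, template, rng):
        crops, asg, truth = [], [], []
        for i in range(30):
            p = int(rng.integers(0, 2))
            crops.append(self._crop(i, p, template))
            hit = bool(rng.random() < 0.5)
            truth.append(hit)
            if hit:
                asg.append(self._hit(i, p))
            elif rng.random() < 0.3:
                asg.append(self._hit(i, 1 - p))  # fixation on *other* person
        fixated, non_fixated = droi.split_fixated_nonfixated(crops, asg)
        assert len(fixated) + len(non_fixated) == len(crops)
        got = {c.crop_id for c in fixated}
        expect = {c.crop_id for c, h in zip(crops, truth) if h}
        assert got == expect


class TestWarpToLandmarks:
    def test_identity_warp(self, template):
        img = _smooth_image((200, 210))
        out = droi.warp_to_landmarks(img, template.landmarks,
                                     template.landmarks, template.triangles,
                                     output_shape=img.shape)
        mask = _hull_mask(img.shape, template.landmarks)
        assert np.abs(out - img)[mask].mean() < 1 / 255

    def test_translation_equivariance(self, template):
        img = _smooth_image((220, 230))
        shift = np.array([15.0, 10.0])
        out = droi.warp_to_landmarks(img, template.landmarks,
                                     template.landmarks + shift,
                                     template.triangles,
                                     output_shape=(240, 250))
        mask = _hull_mask((240, 250), template.landmarks + shift, erode=4)
        yy, xx = np.mgrid[0:240, 0:250]
        src = np.clip(yy - shift[1], 0, 219).astype(int), \
            np.clip(xx - shift[0], 0, 229).astype(int)
        assert np.abs(out - img[src])[mask].mean() < 1 / 255

    def test_affine_round_trip(self, template, rng):
        img = _smooth_image((200, 210))
        a = np.array([[1.05, 0.05], [-0.04, 0.97]])
        b = np.array([4.0, 6.0])
        warped_lm = template.landmarks @ a.T + b
        fwd = droi.warp_to_landmarks(img, template.landmarks, warped_lm,
                                     template.triangles,
                                     output_shape=(220, 230))
        back = droi.warp_to_landmarks(fwd, warped_lm, template.landmarks,
                                      template.triangles,
                                      output_shape=img.shape)
        mask = _hull_mask(img.shape, template.landmarks, erode=5)
        assert np.abs(back - img)[mask].mean() < 2 / 255

    def test_matches_skimage_piecewise_affine(self, template):
        # independent implementation: skimage estimates its own
        # piecewise-affine map from the same correspondences
        skimage_tf = pytest.importorskip("skimage.transform")
        img = _smooth_image((200, 210))
        a = np.array([[0.96, 0.03], [0.02, 1.04]])
        dst_lm = template.landmarks @ a.T + np.array([3.0, -2.0])
        ours = droi.warp_to_landmarks(img, template.landmarks, dst_lm,
                                      template.triangles,
                                      output_shape=img.shape)
        tf = skimage_tf.PiecewiseAffineTransform.from_estimate(
            dst_lm, template.landmarks)
        theirs = skimage_tf.warp(img, tf, output_shape=img.shape,
                                 cval=0.5, order=1)
        mask = _hull_mask(img.shape, dst_lm, erode=5)
        assert np.abs(ours - theirs)[mask].mean() < 2 / 255

    def test_degenerate_triangle_names_triangle(self, template):
        bad = template.landmarks.copy()
        tri0 = template.triangles[0]
        bad[tri0[1]] = bad[tri0[0]]
        bad[tri0[2]] = bad[tri0[0]]
        with pytest.raises(GeometryError, match="triangle 0"):
            droi.warp_to_landmarks(_smooth_image((200, 200)),
                                   template.landmarks, bad,
                                   template.triangles)


class TestAverageFaces:
    def _crop(self, value, template, cid="c"):
        img = np.full((200, 210), float(value))
        return droi.FaceCrop(crop_id=cid, image=img,
                             landmarks=template.landmarks.copy())

    def test_singleton_average_reproduces_crop(self, template):
        img = _smooth_image((200, 210))
        crop = droi.FaceCrop(crop_id="c", image=img,
                             landmarks=template.landmarks.copy())
        avg = droi.average_faces({0: [crop]}, template,
                                 output_shape=img.shape)
        mask = _hull_mask(img.shape, template.landmarks, erode=4)
        assert np.abs(avg.image - img)[mask].mean() < 1 / 255

    def test_equal_identity_contribution(self, template):
        # identity A: five crops of 0.2; identity B: one crop of 0.6
        groups = {
            0: [self._crop(0.2, template, f"a{i}") for i in range(5)],
            1: [self._crop(0.6, template, "b0")],
        }
        avg = droi.average_faces(groups, template, condition="fixated")
        mask = _hull_mask(avg.image.shape, template.landmarks, erode=4)
        assert avg.image[mask].mean() == pytest.approx(0.4, abs=1 / 255)
        assert avg.n_identities == 2

    def test_duplicating_crops_leaves_average_unchanged(self, template,
                                                        rng):
        imgs = [np.clip(_smooth_image((200, 210), rng), 0, 1)
                for _ in range(2)]
        crops = [droi.FaceCrop(crop_id=f"c{i}", image=im,
                               landmarks=template.landmarks.copy())
                 for i, im in enumerate(imgs)]
        a = droi.average_faces({0: [crops[0]], 1: [crops[1]]}, template)
        b = droi.average_faces({0: [crops[0]] * 3, 1: [crops[1]]}, template)
        mask = _hull_mask(a.image.shape, template.landmarks, erode=4)
        assert np.abs(a.image - b.image)[mask].max() < 1 / 255

    def test_empty_identity_rejected(self, template):
        with pytest.raises(ValueError):
            droi.average_faces({0: []}, template)
        with pytest.raises(ValueError):
            droi.average_faces({}, template)
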