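import numpy as np
import pytest
from scipy import stats

import droi
from conftest import make_body, make_face


def _assign(roi, frame_index, fid=0, person=0, fx=0.0, fy=0.0):
    person_index = None if roi == "non_person" else person
    return droi.FixationAssignment(
        fixation_id=fid, frame_index=frame_index, roi=roi,
        person_index=person_index,
        landmark_kind=None if person_index is None else "body",
        landmark_index=None if person_index is None else 0,
        distance_px=None if person_index is None else 1.0,
        fix_x=fx, fix_y=fy)


def _frames(detected_indices, all_indices, rng):
    out = {}
    for i in all_indices:
        if i in detected_indices:
            out[i] = droi.FrameDetections(
                i, bodies=[make_body(rng.uniform(0, 100, (25, 2)))])
        else:
            out[i] = droi.FrameDetections(i)
    return out


class TestSummarizeAttention:
    def test_hand_counts_both_modes(self, rng):
        # 10 fixation-frames: 2 head, 3 body, 5 non-person; of these, 6
        # frames have surviving detections (2 head, 3 body, 1 non-person)
        rois = ["head"] * 2 + ["body"] * 3 + ["non_person"] * 5
        assignments = [_assign(r, i, fid=i) for i, r in enumerate(rois)]
        detected = set(range(6))
        frames = _frames(detected, range(10), rng)

        s_all = droi.summarize_attention(assignments, frames,
                                         "all_fixation_frames")
        assert (s_all.p_head, s_all.p_body, s_all.p_nonperson) == \
            (0.2, 0.3, 0.5)
        s_det = droi.summarize_attention(assignments, frames,
                                         "detected_frames")
        assert (s_det.p_head, s_det.p_body, s_det.p_nonperson) == \
            (2 / 6, 3 / 6, 1 / 6)

    def test_all_head_degenerate(self, rng):
        assignments = [_assign("head", i) for i in range(4)]
        frames = _frames(set(range(4)), range(4), rng)
        s = droi.summarize_attention(assignments, frames)
        assert (s.p_head, s.p_body, s.p_nonperson) == (1.0, 0.0, 0.0)

    def test_facial_regions_count_as_head(self, rng):
        assignments = [_assign("nose", 0), _assign("mouth", 1)]
        frames = _frames({0, 1}, range(2), rng)
        s = droi.summarize_attention(assignments, frames)
        assert s.p_head == 1.0

    def test_detected_mode_never_below_all_mode(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            rois = r.choice(["head", "body", "non_person"], size=30)
            assignments = [_assign(roi, i, fid=i)
                           for i, roi in enumerate(rois)]
            detected = set(r.choice(30, size=15, replace=False).tolist()) \
                | {i for i, roi in enumerate(rois) if roi != "non_person"}
            frames = _frames(detected, range(30), rng)
            s_all = droi.summarize_attention(assignments, frames,
                                             "all_fixation_frames")
            s_det = droi.summarize_attention(assignments, frames,
                                             "detected_frames")
            assert s_det.p_head >= s_all.p_head - 1e-12
            assert s_det.p_body >= s_all.p_body - 1e-12
            for s in (s_all, s_det):
                assert s.p_head + s.p_body + s.p_nonperson == \
                    pytest.approx(1.0, abs=1e-12)

    def test_empty_denominator_is_error(self, rng):
        assignments = [_assign("non_person", 0)]
        frames = _frames(set(), [0], rng)
        with pytest.raises(ValueError):
            droi.summarize_attention(assignments, frames, "detected_frames")


def _face_at(template, scale, offset, person_index=0):
    pts = template.landmarks * scale + np.asarray(offset)
    return make_face(pts, person_index=person_index)


class TestStratifyByFaceSize:
    def test_two_face_widths_force_partition(self, template, camera):
        # faces of 1 and 3 degrees: mean split 2 deg separates frames
        # exactly by which face is present
        w1 = droi.deg_to_px(1.0, camera) / 160.0
        w3 = droi.deg_to_px(3.0, camera) / 160.0
        frames = {
            0: droi.FrameDetections(0, faces=[_face_at(template, w1, (100, 100))]),
            1: droi.FrameDetections(1, faces=[_face_at(template, w3, (500, 100))]),
        }
        assignments = [_assign("head", 0, fx=110, fy=110),
                       _assign("head", 1, fid=1, fx=510, fy=110)]
        res = droi.stratify_by_face_size(assignments, frames, camera)
        assert res.above is not None and res.above.n_frames == 1
        assert res.below is not None and res.below.n_frames == 1
        assert 1.0 < res.split_deg < 3.0

    def test_equal_widths_leave_above_stratum_empty(self, template, camera):
        scale = droi.deg_to_px(2.0, camera) / 160.0
        frames = {i: droi.FrameDetections(
            i, faces=[_face_at(template, scale, (100, 100))])
            for i in range(3)}
        assignments = [_assign("head", i, fid=i, fx=150, fy=150)
                       for i in range(3)]
        res = droi.stratify_by_face_size(assignments, frames, camera)
        assert res.above is None
        assert res.below.n_frames == 3

    def test_stratum_proportions_match_recount(self, template, camera, rng):
        scales = {0: 1.0, 1: 3.0}
        frames, assignments = {}, []
        truth = []
        for i in range(40):
            deg = scales[i % 2]
            scale = droi.deg_to_px(deg, camera) / 160.0
            frames[i] = droi.FrameDetections(
                i, faces=[_face_at(template, scale, (100, 100))])
            roi = str(rng.choice(["head", "body", "non_person"]))
            assignments.append(_assign(roi, i, fid=i, fx=150, fy=150))
            truth.append((deg, roi))
        res = droi.stratify_by_face_size(assignments, frames, camera)
        big = [r for d, r in truth if d == 3.0]
        assert res.above.p_head == pytest.approx(
            big.count("head") / len(big))
        assert res.above.n_frames == len(big)

    def test_no_measurable_faces_is_error(self, camera, rng):
        frames = _frames({0}, [0], rng)  # bodies only
        with pytest.raises(ValueError):
            droi.stratify_by_face_size([_assign("head", 0)], frames, camera)


class TestConditionTable:
    def _vis(self, frame, status, person=0):
        return droi.FaceVisibility(frame_index=frame, person_index=person,
                                   status=status)

    def test_planted_20_frame_hand_counts(self):
        # frames 0-9 full (4 head, 4 body, 2 non-person), 10-19 partial
        # (1 head, 5 body, 4 non-person)
        rois = (["head"] * 4 + ["body"] * 4 + ["non_person"] * 2
                + ["head"] * 1 + ["body"] * 5 + ["non_person"] * 4)
        assignments = [_assign(r, i, fid=i) for i, r in enumerate(rois)]
        vis = [self._vis(i, "full" if i < 10 else "partial")
               for i in range(20)]
        table = droi.condition_table_full_partial(assignments, vis)
        assert table["full"] == {"p_head": 0.4, "p_body": 0.4, "n_frames": 10}
        assert table["partial"] == {"p_head": 0.1, "p_body": 0.5,
                                    "n_frames": 10}

    def test_swapping_labels_swaps_columns(self):
        rois = ["head", "body", "non_person", "head"]
        assignments = [_assign(r, i, fid=i) for i, r in enumerate(rois)]
        vis = [self._vis(i, s) for i, s in
               enumerate(["full", "full", "partial", "partial"])]
        flipped = [self._vis(i, {"full": "partial", "partial": "full"}[v.status])
                   for i, v in enumerate(vis)]
        t1 = droi.condition_table_full_partial(assignments, vis)
        t2 = droi.condition_table_full_partial(assignments, flipped)
        assert t1["full"] == t2["partial"] and t1["partial"] == t2["full"]

    def test_single_condition_leaves_other_undefined(self):
        assignments = [_assign("head", 0)]
        table = droi.condition_table_full_partial(
            assignments, [self._vis(0, "full")])
        assert table["partial"] is None
        assert table["full"]["p_head"] == 1.0

    def test_frames_without_faces_are_excluded(self):
        assignments = [_assign("head", 0), _assign("body", 5)]
        table = droi.condition_table_full_partial(
            assignments, [self._vis(0, "full")])
        assert table["full"]["n_frames"] == 1


class TestSplitHalfCorrelation:
    def test_identity_is_one(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5]
        res = droi.split_half_correlation(x, x)
        assert res.rho == pytest.approx(1.0)

    def test_reversed_ranks_is_minus_one(self):
        x = [1, 2, 3, 4, 5]
        res = droi.split_half_correlation(x, x[::-1])
        assert res.rho == pytest.approx(-1.0)

    def test_five_point_hand_value(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4; rho = 1 - 6*4/(5*24) = 0.8
        res = droi.split_half_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.ci_low <= res.rho <= res.ci_high
        assert res.n == 5

    def test_ci_uses_rank_corrected_fisher_z(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = droi.split_half_correlation(x, y)
        z = np.arctanh(res.rho)
        se = np.sqrt(1.06 / 27)
        assert res.ci_low == pytest.approx(np.tanh(z - 1.959963984540054 * se))
        assert res.ci_high == pytest.approx(np.tanh(z + 1.959963984540054 * se))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            droi.split_half_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            droi.split_half_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialSpearman:
    def test_covariate_equal_to_y_gives_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert droi.partial_spearman(x, y, y) == pytest.approx(0.0, abs=1e-12)

    def test_independent_covariate_changes_little(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = x + 0.5 * rng.normal(size=200)
        z = rng.normal(size=200)
        plain = stats.spearmanr(x, y).statistic
        assert droi.partial_spearman(x, y, z) == pytest.approx(plain,
                                                              abs=0.05)

    def test_matches_independent_oracle(self):
        # pingouin implements partial correlation independently
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "x": rng.normal(size=25),
            "z": rng.normal(size=25),
        })
        df["y"] = df.x * 0.7 + df.z * 0.5 + rng.normal(size=25)
        ours = droi.partial_spearman(df.x, df.y, df.z)
        theirs = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                       method="spearman")["r"].iloc[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_six_point_three_rho_formula(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        z = [1, 3, 2, 5, 4, 6]
        r_xy = stats.spearmanr(x, y).statistic
        r_xz = stats.spearmanr(x, z).statistic
        r_yz = stats.spearmanr(y, z).statistic
        expect = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert droi.partial_spearman(x, y, z) == pytest.approx(expect)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            droi.partial_spearman([1, 2, 3], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            droi.partial_spearman([1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1])
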