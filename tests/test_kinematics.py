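import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from orthofusion.kinematics import (
    Pose,
    PoseTrack,
    UnitQuaternion,
    compose,
    ncc_error,
    orientation_error,
    position_error,
    read_ncc_series,
    read_pose_tracks,
    relative_pose,
    summarize_trial,
    write_pose_tracks,
)


def random_quaternion(rng):
    return UnitQuaternion(*rng.normal(size=4))


def random_pose(rng):
    return Pose(random_quaternion(rng), rng.normal(scale=20, size=3))


class TestOrientationError:
    def test_identical_rotations_zero(self, rng):
        q = random_quaternion(rng)
        assert orientation_error(q, q) == 0.0

    def test_double_cover_invariance(self, rng):
        q = random_quaternion(rng)
        neg = UnitQuaternion(*(-q.q))
        # arccos near 1 amplifies 1-ulp renormalization noise to ~1e-6 deg
        assert orientation_error(q, neg) < 1e-5

    def test_ninety_degrees_about_z(self):
        p = UnitQuaternion.identity()
        q = UnitQuaternion.from_axis_angle((0, 0, 1), 90.0)
        assert orientation_error(p, q) == pytest.approx(90.0, abs=1e-9)

    def test_agrees_with_rotation_library(self, rng):
        """Cross-check against scipy's rotation geodesic magnitude."""
        for _ in range(30):
            p, q = random_quaternion(rng), random_quaternion(rng)
            rp = Rotation.from_quat(np.roll(p.q, -1))  # scipy is scalar-last
            rq = Rotation.from_quat(np.roll(q.q, -1))
            expected = np.degrees((rp.inv() * rq).magnitude())
            assert orientation_error(p, q) == pytest.approx(expected, abs=1e-9)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(50):
            p, q, r = (random_quaternion(rng) for _ in range(3))
            assert orientation_error(p, q) == pytest.approx(orientation_error(q, p))
            assert (
                orientation_error(p, r)
                <= orientation_error(p, q) + orientation_error(q, r) + 1e-9
            )

    def test_left_invariance(self, rng):
        for _ in range(20):
            p, q, r = (random_quaternion(rng) for _ in range(3))
            assert orientation_error(r * p, r * q) == pytest.approx(
                orientation_error(p, q), abs=1e-9
            )

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            UnitQuaternion(0, 0, 0, 0)


class TestPositionError:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((1, 2, 3), (1, 2, 3), 0.0), ((1, 0, 0), (0, 0, 0), 1.0), ((1, 2, 2), (0, 0, 0), 3.0)],
    )
    def test_examples(self, a, b, expected):
        assert position_error(a, b) == pytest.approx(expected)

    def test_translation_invariance(self, rng):
        a, b, offset = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
        assert position_error(a + offset, b + offset) == pytest.approx(
            position_error(a, b)
        )


class TestNCCError:
    @pytest.mark.parametrize(
        "case,ref,expected", [(0.5, 0.5, 0.0), (0.6, 0.5, 0.2), (0.4, 0.5, -0.2)]
    )
    def test_examples(self, case, ref, expected):
        assert ncc_error(case, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ncc_error(0.5, 0.0)


class TestRelativePose:
    def test_identical_poses_give_identity(self, rng):
        pose = random_pose(rng)
        rel = relative_pose(pose, pose)
        assert abs(rel.rotation.q[0]) == pytest.approx(1.0)
        np.testing.assert_allclose(rel.translation, 0.0, atol=1e-9)

    def test_identity_parent_passes_child_through(self, rng):
        child = random_pose(rng)
        rel = relative_pose(Pose(UnitQuaternion.identity(), (0, 0, 0)), child)
        np.testing.assert_allclose(rel.translation, child.translation)
        assert orientation_error(rel.rotation, child.rotation) == pytest.approx(0, abs=1e-9)

    def test_compose_round_trip(self, rng):
        """parent o relative_pose(parent, child) reproduces child to 1e-9."""
        for _ in range(30):
            parent, child = random_pose(rng), random_pose(rng)
            back = compose(parent, relative_pose(parent, child))
            np.testing.assert_allclose(back.translation, child.translation, atol=1e-9)
            # compare components up to the quaternion sign ambiguity
            delta = min(
                np.abs(back.rotation.q - child.rotation.q).max(),
                np.abs(back.rotation.q + child.rotation.q).max(),
            )
            assert delta < 1e-9


class TestSummarizeTrial:
    def make_tracks(self, rng, n_frames=12):
        parent = PoseTrack("C5", [random_pose(rng) for _ in range(n_frames)])
        child = PoseTrack("C4", [random_pose(rng) for _ in range(n_frames)])
        return parent, child

    def test_identical_tracks_all_zero(self, rng):
        parent, child = self.make_tracks(rng)
        ncc = np.full(len(parent), 0.8)
        s = summarize_trial(parent, child, parent, child, ncc, ncc)
        assert s.orientation_mean_deg == pytest.approx(0.0, abs=1e-6)
        assert s.position_mean_mm == pytest.approx(0.0, abs=1e-9)
        assert s.ncc_error_mean == 0.0 and s.ncc_error_std == 0.0

    def test_constant_orientation_offset(self, rng):
        """A fixed 5-degree relative offset yields mean 5, std 0."""
        parent, child = self.make_tracks(rng)
        offset = UnitQuaternion.from_axis_angle((1, 0, 0), 5.0)
        child_case = PoseTrack(
            "C4", [Pose(p.rotation * offset, p.translation) for p in child.poses]
        )
        s = summarize_trial(parent, child_case, parent, child)
        assert s.orientation_mean_deg == pytest.approx(5.0, abs=1e-7)
        assert s.orientation_std_deg == pytest.approx(0.0, abs=1e-7)

    def test_matches_brute_force_recomputation(self, rng):
        case_p, case_c = self.make_tracks(rng)
        ref_p, ref_c = self.make_tracks(rng)
        ncc_case = rng.uniform(0.3, 0.9, len(case_p))
        ncc_ref = rng.uniform(0.3, 0.9, len(case_p))
        s = summarize_trial(case_p, case_c, ref_p, ref_c, ncc_case, ncc_ref)
        ori, pos = [], []
        for i in range(len(case_p)):
            qc = case_p.poses[i].rotation.conjugate() * case_c.poses[i].rotation
            qr = ref_p.poses[i].rotation.conjugate() * ref_c.poses[i].rotation
            ori.append(np.degrees(2 * np.arccos(min(1.0, abs(np.dot(qc.q, qr.q))))))
            tc = case_p.poses[i].rotation.conjugate().rotate(
                case_c.poses[i].translation - case_p.poses[i].translation
            )
            tr = ref_p.poses[i].rotation.conjugate().rotate(
                ref_c.poses[i].translation - ref_p.poses[i].translation
            )
            pos.append(np.linalg.norm(tc - tr))
        nccs = (ncc_case - ncc_ref) / ncc_ref
        assert s.orientation_mean_deg == pytest.approx(np.mean(ori))
        assert s.orientation_std_deg == pytest.approx(np.std(ori, ddof=1))
        assert s.position_mean_mm == pytest.approx(np.mean(pos))
        assert s.position_std_mm == pytest.approx(np.std(pos, ddof=1))
        assert s.ncc_error_mean == pytest.approx(nccs.mean())
        assert s.ncc_error_std == pytest.approx(np.std(nccs, ddof=1))

    def test_frame_count_mismatch_rejected(self, rng):
        p, c = self.make_tracks(rng, 10)
        p2, c2 = self.make_tracks(rng, 11)
        with pytest.raises(ValueError, match="frame"):
            summarize_trial(p, c, p2, c2)


def test_pose_csv_round_trip(tmp_path, rng):
    tracks = {
        "C4": PoseTrack("C4", [random_pose(rng) for _ in range(5)]),
        "C5": PoseTrack("C5", [random_pose(rng) for _ in range(5)]),
    }
    path = tmp_path / "poses.csv"
    write_pose_tracks(tracks, path)
    back = read_pose_tracks(path)
    assert set(back) == {"C4", "C5"}
    for bone in tracks:
        for a, b in zip(tracks[bone].poses, back[bone].poses):
            np.testing.assert_allclose(a.rotation.q, b.rotation.q, atol=1e-12)
            np.testing.assert_allclose(a.translation, b.translation, atol=1e-12)


def test_ncc_csv_reader(tmp_path):
    path = tmp_path / "ncc.csv"
    path.write_text("frame,ncc\n1,0.5\n0,0.7\n2,0.6\n")
    np.testing.assert_allclose(read_ncc_series(path), [0.7, 0.5, 0.6])
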