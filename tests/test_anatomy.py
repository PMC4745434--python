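import numpy as np
import pytest

from gaitkin.anatomy import (LandmarkSet, MissingLandmarkError, build_hh_frames,
                             build_isb_frames, chord_joint_centre,
                             davis_hip_joint_centre, pelvis_frame)
from gaitkin.kinematics import cardan_decompose, relative_rotation
from gaitkin.rigid_body import GeometryError, Pose
from gaitkin.synthetic import SyntheticSubject, forward_kinematics

from conftest import random_rotations


class TestDavisRegression:
    def test_hand_evaluated_instance(self):
        """Frozen against an independent hand evaluation of the published
        regression (C = 0.115 L - 15.3, theta = 28.4 deg, beta = 18 deg) for
        L = 900, inter-ASIS = 250, ASIS-trochanter 70, marker radius 7 mm."""
        hjc = davis_hip_joint_centre(900.0, 250.0, asis_trochanter_offset=70.0,
                                     marker_radius=7.0, side="right")
        assert np.allclose(hjc.local,
                           [-49.2562669708842, -97.58203230848432,
                            83.04994476000172], atol=1e-9)

    def test_left_right_mirror(self):
        r = davis_hip_joint_centre(880.0, 240.0, side="right")
        l = davis_hip_joint_centre(880.0, 240.0, side="left")
        assert np.allclose(r.local * [1, 1, -1], l.local)
        assert r.local[2] > 0 > l.local[2]

    def test_leg_length_terms_scale_linearly(self):
        """Doubling leg length doubles exactly the C- and offset-dependent
        terms; verified against the closed form with the default
        ASIS-trochanter estimate 0.1288 L - 48.56."""
        d, r = 250.0, 0.0
        th, be = np.deg2rad(28.4), np.deg2rad(18.0)
        for L in (800.0, 1600.0):
            C = 0.115 * L - 15.3
            xd = 0.1288 * L - 48.56
            expected = np.array([
                C * np.cos(th) * np.sin(be) - xd * np.cos(be),
                -C * np.cos(th) * np.cos(be) - xd * np.sin(be),
                d / 2 - C * np.sin(th)])
            got = davis_hip_joint_centre(L, d, side="right").local
            assert np.allclose(got, expected, atol=1e-9)

    def test_marker_radius_term_isolated(self):
        base = davis_hip_joint_centre(900.0, 250.0, asis_trochanter_offset=70.0,
                                      marker_radius=0.0).local
        with_r = davis_hip_joint_centre(900.0, 250.0, asis_trochanter_offset=70.0,
                                        marker_radius=10.0).local
        diff = with_r - base
        # radius enters only through the (offset + r) terms: -r cos(beta),
        # -r sin(beta), nothing lateral
        assert diff[0] == pytest.approx(-10 * np.cos(np.deg2rad(18)), abs=1e-9)
        assert diff[1] == pytest.approx(-10 * np.sin(np.deg2rad(18)), abs=1e-9)
        assert diff[2] == 0.0

    def test_nonpositive_anthropometrics_rejected(self):
        with pytest.raises(ValueError):
            davis_hip_joint_centre(-1.0, 250.0)
        with pytest.raises(ValueError):
            davis_hip_joint_centre(900.0, 0.0)


def _neutral_landmarks(subject: SyntheticSubject, pose: Pose | None = None):
    """All landmarks of the synthetic skeleton in its neutral stance."""
    zeros = np.zeros((1, 12))
    t_pel = np.array([[0.0, subject.pelvis_height, 0.0]])
    _, _, lands = forward_kinematics(subject, zeros, t_pel)
    flat = {name: arr for seg in lands for name, arr in lands[seg].items()}
    ls = LandmarkSet(flat, {k: np.array([True]) for k in flat})
    return ls.transformed(pose) if pose else ls


class TestIsbFrames:
    def test_pelvis_frame_recovered_exactly(self):
        """ASIS markers on the Z axis and symmetric PSIS landmarks give the
        identity pelvis orientation with X anterior."""
        sub = SyntheticSubject()
        lm = _neutral_landmarks(sub)
        frames = build_isb_frames(lm, _hjc(sub), neutral_reference=lm)
        R = frames["pelvis"].rotations[0]
        assert np.abs(R - np.eye(3)).max() < 1e-12
        assert np.allclose(frames["pelvis"].translations[0],
                           [0, sub.pelvis_height, 0])

    def test_all_neutral_frames_recovered(self):
        """On the noise-free synthetic skeleton every anatomical frame equals
        the segment frame it was generated from."""
        sub = SyntheticSubject()
        lm = _neutral_landmarks(sub)
        frames = build_isb_frames(lm, _hjc(sub), neutral_reference=lm)
        for seg in ("pelvis", "femur", "shank", "foot"):
            R = frames[seg].rotations[0]
            assert np.abs(R - np.eye(3)).max() < 1e-9, seg

    def test_neutral_foot_equals_shank_frame(self):
        sub = SyntheticSubject()
        lm = _neutral_landmarks(sub)
        frames = build_isb_frames(lm, _hjc(sub), neutral_reference=lm)
        rel = relative_rotation(frames["shank"].rotations[0],
                                frames["foot"].rotations[0])
        assert np.abs(rel - np.eye(3)).max() < 1e-10

    def test_equivariance_under_rigid_motion(self):
        """Rigidly transforming all landmarks transforms every frame by the
        same motion (orientations compose; origins map through the motion)."""
        sub = SyntheticSubject()
        lm = _neutral_landmarks(sub)
        base = build_isb_frames(lm, _hjc(sub), neutral_reference=lm)
        for k in range(10):
            motion = Pose(random_rotations(1, seed=100 + k)[0],
                          np.random.default_rng(k).normal(scale=400, size=3))
            moved = build_isb_frames(lm.transformed(motion), _hjc(sub),
                                     neutral_reference=lm.transformed(motion))
            for seg in ("pelvis", "femur", "shank", "foot"):
                assert np.allclose(moved[seg].rotations[0],
                                   motion.rotation @ base[seg].rotations[0],
                                   atol=1e-9)
                assert np.allclose(moved[seg].translations[0],
                                   motion.apply(base[seg].translations[0]),
                                   atol=1e-7)

    def test_frames_orthonormal_right_handed(self):
        sub = SyntheticSubject()
        motion = Pose(random_rotations(1, seed=77)[0], np.array([10.0, 5, -3]))
        lm = _neutral_landmarks(sub, motion)
        frames = build_isb_frames(lm, _hjc(sub), neutral_reference=lm)
        for seg, ps in frames.items():
            R = ps.rotations[0]
            assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-9
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_missing_landmark_names_segment(self):
        sub = SyntheticSubject()
        lm = _neutral_landmarks(sub)
        del lm.positions["R_MFE"], lm.valid["R_MFE"]
        with pytest.raises(MissingLandmarkError, match="R_MFE.*femur"):
            build_isb_frames(lm, _hjc(sub), neutral_reference=lm)

    def test_degenerate_pelvis_geometry(self):
        p = np.zeros((1, 3))
        with pytest.raises(GeometryError, match="pelvis"):
            pelvis_frame(p, p, p + [[1.0, 0, 0]], np.array([True]))


def _hjc(sub: SyntheticSubject):
    return davis_hip_joint_centre(sub.leg_length, sub.inter_asis,
                                  marker_radius=sub.marker_radius, side="right")


class TestHelenHayesFrames:
    def test_wand_in_frontal_plane_matches_isb_femur(self):
        """With the thigh wand exactly in the true frontal plane, the HH femur
        frame coincides with the ISB femur frame on the same skeleton."""
        sub = SyntheticSubject()
        lm = _neutral_landmarks(sub)
        isb = build_isb_frames(lm, _hjc(sub), neutral_reference=lm)
        hh = build_hh_frames(lm, _hjc(sub), sub.knee_width, sub.ankle_width)
        rel = relative_rotation(isb["femur"].rotations[0],
                                hh["femur"].rotations[0])
        a, b, g, _ = cardan_decompose(rel)
        assert max(abs(a), abs(b), abs(g)) < 1e-6

    def test_wand_rotation_shifts_axial_alignment(self):
        """Rotating the wand ~10 deg off the frontal plane (about the thigh
        long axis) rotates the HH femur frame axially by about as much."""
        sub = SyntheticSubject(crosstalk_deg=10.0)
        lm = _neutral_landmarks(sub)
        isb = build_isb_frames(lm, _hjc(sub), neutral_reference=lm)
        hh = build_hh_frames(lm, _hjc(sub), sub.knee_width, sub.ankle_width)
        rel = relative_rotation(isb["femur"].rotations[0],
                                hh["femur"].rotations[0])
        a, b, g, _ = cardan_decompose(rel)
        assert 6.0 < abs(g) < 16.0          # axial offset of wand-order size
        assert abs(a) < 2.0 and abs(b) < 2.0

    def test_missing_thigh_wand_named(self):
        sub = SyntheticSubject()
        lm = _neutral_landmarks(sub)
        del lm.positions["R_THIGH_WAND"], lm.valid["R_THIGH_WAND"]
        with pytest.raises(MissingLandmarkError, match="R_THIGH_WAND"):
            build_hh_frames(lm, _hjc(sub), sub.knee_width, sub.ankle_width)

    def test_chord_centre_geometry(self):
        """The chord joint centre lies at the requested offset from the
        lateral marker, perpendicular to the long axis, medial of the wand."""
        prox = np.array([[0.0, 0.0, 0.0]])
        lat = np.array([[0.0, -420.0, 55.0]])
        wand = np.array([[0.0, -200.0, 130.0]])
        jc = chord_joint_centre(prox, lat, wand, 55.0)
        assert np.allclose(jc, [[0.0, -420.0, 0.0]], atol=1e-9)
        assert np.dot((jc - lat)[0], (jc - prox)[0]) == pytest.approx(0, abs=1e-9)

    def test_chord_collinear_wand_rejected(self):
        prox = np.array([[0.0, 0.0, 0.0]])
        lat = np.array([[0.0, -420.0, 0.0]])
        wand = np.array([[0.0, -210.0, 0.0]])
        with pytest.raises(GeometryError, match="collinear"):
            chord_joint_centre(prox, lat, wand, 55.0)
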