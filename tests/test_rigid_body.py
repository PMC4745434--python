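import numpy as np
import pytest

from gaitkin.rigid_body import (CalibrationError, GeometryError, Pose,
                                PoseSeries, fit_rigid_transform,
                                pivot_calibrate, reconstruct_virtual_marker,
                                register_landmark)

from conftest import random_rotations

TRIAD = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 100.0, 0.0]])


class TestFitRigidTransform:
    def test_identity_on_identical_points(self):
        pose, rms = fit_rigid_transform(TRIAD, TRIAD)
        assert np.allclose(pose.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(pose.translation, 0, atol=1e-12)
        assert rms < 1e-12

    def test_recovers_constructed_transform(self):
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([1.0, 2.0, 3.0])
        ref = np.eye(3)  # unit triad
        pose, rms = fit_rigid_transform(ref, ref @ R.T + t)
        assert np.abs(pose.rotation - R).max() < 1e-12
        assert np.abs(pose.translation - t).max() < 1e-12

    def test_exact_on_random_transforms(self):
        """1000 random rigid motions of a noise-free cluster recovered to 1e-10."""
        Rs = random_rotations(1000, seed=3)
        g = np.random.default_rng(4)
        ref = g.normal(scale=100.0, size=(5, 3))
        ts = g.normal(scale=500.0, size=(1000, 3))
        worst = 0.0
        for R, t in zip(Rs, ts):
            pose, rms = fit_rigid_transform(ref, ref @ R.T + t)
            worst = max(worst, np.abs(pose.rotation - R).max(),
                        np.abs(pose.translation - t).max() / 1000, rms)
        assert worst < 1e-10

    def test_noise_monte_carlo(self):
        """sigma=0.5 mm noise on a 100 mm triad: <1 deg rotation error, RMS ~ sigma."""
        g = np.random.default_rng(5)
        sigma = 0.5
        rot_errs, rmss = [], []
        for _ in range(1000):
            obs = TRIAD + g.normal(scale=sigma, size=TRIAD.shape)
            pose, rms = fit_rigid_transform(TRIAD, obs)
            angle = np.degrees(np.arccos(np.clip((np.trace(pose.rotation) - 1) / 2,
                                                 -1, 1)))
            rot_errs.append(angle)
            rmss.append(rms)
        assert np.mean(rot_errs) < 1.0
        assert np.percentile(rot_errs, 99) < 3.0
        assert 0.2 * sigma < np.mean(rmss) < 1.2 * sigma

    def test_collinear_reference_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(GeometryError, match="collinear"):
            fit_rigid_transform(line, line)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_rigid_transform(TRIAD[:2], TRIAD[:2])

    def test_pose_invariants_on_fitted_poses(self):
        g = np.random.default_rng(6)
        for _ in range(50):
            obs = TRIAD + g.normal(scale=2.0, size=TRIAD.shape)
            pose, _ = fit_rigid_transform(TRIAD, obs)
            assert np.linalg.norm(pose.rotation.T @ pose.rotation - np.eye(3)) < 1e-9
            assert abs(np.linalg.det(pose.rotation) - 1) < 1e-9


def _pivot_poses(tip, pivot, n=200, noise=0.0, seed=0):
    Rs = random_rotations(n, seed=seed)
    g = np.random.default_rng(seed + 1)
    ds = pivot - np.einsum("nij,j->ni", Rs, tip)
    if noise:
        ds = ds + g.normal(scale=noise, size=ds.shape)
    return [Pose(R, d) for R, d in zip(Rs, ds)]


class TestPivotCalibration:
    tip = np.array([130.0, -20.0, 15.0])
    pivot = np.array([250.0, 100.0, 900.0])

    def test_exact_recovery(self):
        model = pivot_calibrate(_pivot_poses(self.tip, self.pivot))
        assert np.abs(model.tip_offset - self.tip).max() < 1e-9
        assert model.residual_rms < 1e-9

    def test_noisy_recovery(self):
        model = pivot_calibrate(_pivot_poses(self.tip, self.pivot,
                                             noise=0.2, seed=9))
        assert np.linalg.norm(model.tip_offset - self.tip) < 0.5
        assert model.residual_rms > 0

    def test_pure_translation_unobservable(self):
        poses = [Pose(np.eye(3), np.array([float(i), 0.0, 0.0]))
                 for i in range(50)]
        with pytest.raises(CalibrationError, match="diversity"):
            pivot_calibrate(poses)

    def test_too_few_poses(self):
        with pytest.raises(CalibrationError, match="10"):
            pivot_calibrate(_pivot_poses(self.tip, self.pivot, n=5))


class TestLandmarkRegistration:
    def test_identity_cluster_gives_lab_position(self):
        model = pivot_calibrate(_pivot_poses(np.array([100.0, 0, 0]),
                                             np.array([0.0, 0, 0])))
        ptr_pose = Pose(np.eye(3), np.array([10.0, 20.0, 30.0]))
        local, scatter = register_landmark(model, ptr_pose, Pose.identity())
        tip_lab = ptr_pose.apply(model.tip_offset)
        assert np.allclose(local, tip_lab, atol=1e-9)

    def test_matrix_oracle_for_arbitrary_cluster_pose(self):
        tip = np.array([130.0, -20.0, 15.0])
        model = pivot_calibrate(_pivot_poses(tip, np.array([50.0, 60, 70])))
        R = random_rotations(1, seed=11)[0]
        d = np.array([5.0, -8.0, 12.0])
        ptr_pose = Pose(random_rotations(1, seed=12)[0], np.array([1.0, 2, 3]))
        local, _ = register_landmark(model, ptr_pose, Pose(R, d))
        tip_lab = ptr_pose.apply(model.tip_offset)
        assert np.allclose(local, R.T @ (tip_lab - d), atol=1e-9)

    def test_averaging_reduces_scatter(self):
        """Averaging 64 noisy static frames cuts tip scatter vs a single frame
        by about 1/sqrt(n) (checked as at least 4x over many repeats)."""
        tip = np.array([130.0, -20.0, 15.0])
        model = pivot_calibrate(_pivot_poses(tip, np.array([50.0, 60, 70])))
        g = np.random.default_rng(13)
        n_frames, reps = 64, 60
        singles, averaged = [], []
        truth = np.array([40.0, 50.0, 60.0])
        for _ in range(reps):
            Rs = np.broadcast_to(np.eye(3), (n_frames, 3, 3))
            ds = (truth - tip) + g.normal(scale=0.5, size=(n_frames, 3))
            series = PoseSeries(Rs.copy(), ds, np.ones(n_frames, bool))
            est_avg, _ = register_landmark(model, series, PoseSeries.identity(n_frames))
            one = PoseSeries(Rs[:1].copy(), ds[:1], np.ones(1, bool))
            est_one, _ = register_landmark(model, one, PoseSeries.identity(1))
            averaged.append(np.linalg.norm(est_avg - truth))
            singles.append(np.linalg.norm(est_one - truth))
        assert np.mean(averaged) < np.mean(singles) / 4

    def test_no_common_valid_frame_is_error(self):
        model = pivot_calibrate(_pivot_poses(np.array([100.0, 0, 0]),
                                             np.zeros(3)))
        ptr = PoseSeries.identity(3)
        ptr.valid[:] = [True, False, True]
        clu = PoseSeries.identity(3)
        clu.valid[:] = [False, True, False]
        with pytest.raises(CalibrationError, match="no frame"):
            register_landmark(model, ptr, clu)


class TestVirtualMarkers:
    def test_identity_pose_returns_local(self):
        v = np.array([1.0, 2.0, 3.0])
        out, ok = reconstruct_virtual_marker(v, Pose.identity())
        assert np.allclose(out, v)

    def test_register_then_reconstruct_round_trip(self):
        tip = np.array([130.0, -20.0, 15.0])
        model = pivot_calibrate(_pivot_poses(tip, np.array([50.0, 60, 70])))
        cluster = Pose(random_rotations(1, seed=21)[0], np.array([9.0, 8, 7]))
        ptr = Pose(random_rotations(1, seed=22)[0], np.array([-3.0, 4, 5]))
        local, _ = register_landmark(model, ptr, cluster)
        out, _ = reconstruct_virtual_marker(local, cluster)
        assert np.allclose(out, ptr.apply(model.tip_offset), atol=1e-9)

    def test_equivariance_under_rigid_motion(self):
        """Moving the whole cluster by a rigid transform moves the virtual
        marker by exactly the same transform."""
        local = np.array([10.0, -30.0, 55.0])
        base = Pose(random_rotations(1, seed=31)[0], np.array([100.0, 0, -50]))
        for k in range(20):
            motion = Pose(random_rotations(1, seed=40 + k)[0],
                          np.random.default_rng(60 + k).normal(scale=200, size=3))
            moved = motion.compose(base)
            p0, _ = reconstruct_virtual_marker(local, base)
            p1, _ = reconstruct_virtual_marker(local, moved)
            assert np.allclose(p1, motion.apply(p0), atol=1e-9)

    def test_invalid_frames_stay_invalid(self):
        series = PoseSeries.identity(4)
        series.valid[2] = False
        series.rotations[2] = np.nan
        out, ok = reconstruct_virtual_marker(np.ones(3), series)
        assert not ok[2] and np.isnan(out[2]).all()
        assert ok[[0, 1, 3]].all()
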