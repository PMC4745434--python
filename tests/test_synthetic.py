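import numpy as np
import pytest
import yaml

from gaitkin.kinematics import ROTATION_LABELS, compute_joint_angles
from gaitkin.rigid_body import PoseSeries
from gaitkin.synthetic import (GAIT_TEMPLATES, SimulationConfig,
                               SyntheticSubject, apply_artifacts,
                               evaluate_template, forward_kinematics,
                               generate_angle_curves, generate_study,
                               make_dynamic_trial, segment_label_map,
                               study_offsets)


class TestAngleCurveGeneration:
    def test_zero_dispersion_gives_template(self):
        cfg = SimulationConfig(intertrial_sd_deg=0.0, between_subject_sd_deg=0.0,
                               seed=1)
        phase = np.linspace(0, 1, 101)
        for i, j in [(0, 0), (3, 2)]:
            assert np.array_equal(generate_angle_curves(cfg, i, j, phase),
                                  evaluate_template(phase))

    def test_same_seed_bit_identical(self):
        a = generate_angle_curves(SimulationConfig(seed=5), 1, 2)
        b = generate_angle_curves(SimulationConfig(seed=5), 1, 2)
        c = generate_angle_curves(SimulationConfig(seed=6), 1, 2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_injected_offsets_have_exact_sample_sd(self):
        """The generator standardises the injected effects, so their sample
        variance equals the configured value exactly, for every rotation."""
        cfg = SimulationConfig(n_subjects=6, n_trials=5, intertrial_sd_deg=1.3,
                               between_subject_sd_deg=2.5, seed=3)
        subj, trial = study_offsets(cfg)
        assert np.allclose(subj.std(axis=0, ddof=1), 2.5, atol=1e-10)
        assert np.allclose(trial.std(axis=1, ddof=1), 1.3, atol=1e-10)
        assert np.allclose(trial.mean(axis=1), 0.0, atol=1e-10)

    def test_knee_flexion_template_peak(self):
        curves = evaluate_template(np.linspace(0, 1, 101))
        knee = curves[:, ROTATION_LABELS.index("knee_flexion")]
        assert knee.max() == pytest.approx(60.0, abs=1e-9)
        assert knee.min() == pytest.approx(0.0, abs=1e-9)


class TestForwardKinematics:
    def test_neutral_stack_and_zero_recomputed_angles(self, subject):
        zeros = np.zeros((3, 12))
        t_pel = np.tile([0.0, subject.pelvis_height, 0.0], (3, 1))
        poses, clusters, landmarks = forward_kinematics(subject, zeros, t_pel)
        for seg, (R, t) in poses.items():
            assert np.allclose(R, np.eye(3), atol=1e-12)
        frames = {seg: PoseSeries(R, t, np.ones(3, bool))
                  for seg, (R, t) in poses.items()}
        out = compute_joint_angles(frames)
        assert np.abs(out.values).max() < 1e-10

    def test_round_trip_of_prescribed_angles(self, subject):
        """Decomposing the forward-composed segment poses returns the
        prescribed clinical angles exactly (the generator and the analysis
        share one Cardan convention)."""
        g = np.random.default_rng(4)
        ang = g.uniform(-25, 25, size=(50, 12))
        t_pel = np.tile([0.0, subject.pelvis_height, 0.0], (50, 1))
        poses, _, _ = forward_kinematics(subject, ang, t_pel)
        frames = {seg: PoseSeries(R, t, np.ones(50, bool))
                  for seg, (R, t) in poses.items()}
        out = compute_joint_angles(frames)
        assert np.abs(out.values - ang).max() < 1e-9

    def test_gimbal_range_rejected(self, subject):
        ang = np.zeros((2, 12))
        ang[1, 4] = 89.5   # hip adduction beyond the safe middle-angle range
        with pytest.raises(ValueError, match="gimbal"):
            forward_kinematics(subject, ang,
                               np.tile([0.0, 1000.0, 0.0], (2, 1)))


class TestArtifacts:
    def _trial(self, **kw):
        cfg = SimulationConfig(n_subjects=1, n_trials=1, intertrial_sd_deg=0,
                               between_subject_sd_deg=0, seed=2, **kw)
        sub = SyntheticSubject()
        return sub, cfg, *make_dynamic_trial(sub, cfg, 0, 0)

    def test_zero_amplitudes_identity(self):
        sub, cfg, mset, *_ = self._trial()
        out = apply_artifacts(mset, cfg)
        assert out is mset

    def test_noise_only_angle_error_stays_small(self):
        """0.5 mm marker noise on ~100 mm clusters keeps recovered angle RMSE
        well under 1 degree."""
        from gaitkin.pipeline import analyze_study, load_ground_truth_cycles
        import tempfile
        cfg = SimulationConfig(n_subjects=1, n_trials=1, intertrial_sd_deg=0,
                               between_subject_sd_deg=0, marker_noise_mm=0.5,
                               seed=8)
        d = tempfile.mkdtemp()
        manifest = generate_study(cfg, d)
        study, _ = analyze_study(d, protocols=("ISB6DOF",), cutoff=6.0)
        truth = load_ground_truth_cycles(d, manifest)
        err = study["ISB6DOF"]["S1"][0].values - truth["S1"][0].values
        rmse = np.sqrt((err ** 2).mean(axis=0))
        assert rmse.max() < 1.0

    def test_sta_on_thigh_biases_hip_knee_only(self):
        """Cycle-locked thigh-cluster displacement perturbs hip and knee
        angles but leaves pelvis and ankle untouched (shank and foot frames
        are built from their own clusters)."""
        from gaitkin.pipeline import analyze_study, load_ground_truth_cycles
        import tempfile
        cfg = SimulationConfig(n_subjects=1, n_trials=1, intertrial_sd_deg=0,
                               between_subject_sd_deg=0,
                               sta_amplitude_mm={"femur": 8.0}, seed=9)
        d = tempfile.mkdtemp()
        manifest = generate_study(cfg, d)
        study, _ = analyze_study(d, protocols=("ISB6DOF",), cutoff=None)
        truth = load_ground_truth_cycles(d, manifest)
        err = np.abs(study["ISB6DOF"]["S1"][0].values
                     - truth["S1"][0].values).max(axis=0)
        by = dict(zip(ROTATION_LABELS, err))
        assert max(by["hip_flexion"], by["knee_flexion"]) > 0.5
        assert max(by[k] for k in ("pelvis_tilt", "pelvis_obliquity",
                                   "pelvis_rotation", "ankle_dorsiflexion",
                                   "ankle_inversion", "ankle_adduction")) < 1e-6

    def test_sta_needs_phase_and_labels(self):
        sub, cfg0, mset, *_ = self._trial()
        cfg = SimulationConfig(sta_amplitude_mm={"femur": 5.0}, seed=2)
        with pytest.raises(ValueError, match="phase"):
            apply_artifacts(mset, cfg)


class TestStudyGeneration:
    def test_default_study_shape(self, default_study):
        d, cfg, manifest = default_study
        assert len(manifest["subjects"]) == 4
        dynamic = sorted(p.name for p in d.glob("trial_*.csv"))
        static = sorted(p.name for p in d.glob("static_*.csv"))
        assert len(dynamic) == 12 and len(static) == 4
        assert (d / "manifest.yaml").exists()

    def test_same_seed_byte_identical_manifests(self, tmp_path):
        cfg = SimulationConfig(n_subjects=2, n_trials=2, seed=21)
        generate_study(cfg, tmp_path / "a")
        generate_study(SimulationConfig(n_subjects=2, n_trials=2, seed=21),
                       tmp_path / "b")
        assert (tmp_path / "a" / "manifest.yaml").read_bytes() == \
            (tmp_path / "b" / "manifest.yaml").read_bytes()
        assert (tmp_path / "a" / "trial_S1_T1.csv").read_bytes() == \
            (tmp_path / "b" / "trial_S1_T1.csv").read_bytes()

    def test_ground_truth_files_match_regenerated_curves(self, default_study):
        from gaitkin.io_mocap import read_angle_curves
        d, cfg, manifest = default_study
        tr = manifest["subjects"]["S2"]["trials"][1]
        stored, labels = read_angle_curves(d / tr["truth"])
        assert labels == ROTATION_LABELS
        sub = SyntheticSubject(subject_id="S2")
        _, regenerated, events, _ = make_dynamic_trial(sub, cfg, 1, 1)
        assert np.abs(stored - regenerated).max() < 1e-9
        assert events == tr["events"]

    def test_seed_recorded(self, default_study):
        _, cfg, manifest = default_study
        assert manifest["seed"] == cfg.seed
        assert manifest["config"]["seed"] == cfg.seed

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_subjects=0)
        with pytest.raises(ValueError):
            SimulationConfig(intertrial_sd_deg=-1.0)


class TestTemplates:
    def test_templates_cover_all_rotations(self):
        assert set(GAIT_TEMPLATES) == set(ROTATION_LABELS)

    def test_segment_label_map_covers_clusters_and_markers(self, subject):
        m = segment_label_map(subject)
        assert "PELC1" in m["pelvis"] and "R_ASIS" in m["pelvis"]
        assert "R_THIGH_WAND" in m["femur"]
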