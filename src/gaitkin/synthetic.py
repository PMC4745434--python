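"""Synthetic multi-subject, multi-trial gait marker data by forward kinematics.

The generator replaces study recordings that cannot be shared: it drives an
articulated right lower limb (pelvis, femur, shank, foot) with smooth,
periodic, gait-like joint-angle templates, emits every technical-cluster
marker, skin/wand marker and true anatomical landmark in lab coordinates, and
perturbs them with controllable measurement noise and a cycle-locked
soft-tissue-artefact model.  Because the forward model composes joint
rotations through exactly the same Cardan convention the analysis decomposes,
the noise-free pipeline must reproduce the prescribed angles to numerical
precision — the central identifiability property of the test bed.

Angle templates are truncated cosine series in cycle phase (coefficients
below, degrees).  They are documented fixtures shaped on normative gait
(smooth ~60 deg swing-phase knee flexion peak, small out-of-sagittal
excursions), not claims about any particular cohort.  Pure cosine series have
zero time-derivative at cycle boundaries, which pins the heel's forward
position maximum exactly to the prescribed foot strikes — convenient ground
truth for event detection.

Trial-to-trial and subject-to-subject variation are injected as constant
per-rotation offsets standardised to *exact* sample SD: the trial offsets of
each subject sum to zero with sample SD precisely ``intertrial_sd_deg``, and
the subject offsets have sample SD precisely ``between_subject_sd_deg``, so
the injected dispersion equals the realised one and statistical recovery can
be checked without estimator bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .anatomy import davis_hip_joint_centre
from .io_mocap import MarkerTrajectorySet, MarkerSetConfig, write_trial, \
    write_angle_curves
from .kinematics import ROTATION_LABELS, joint_rotation_matrix, _rx, _ry, _rz

__all__ = [
    "GAIT_TEMPLATES",
    "SyntheticSubject",
    "SimulationConfig",
    "generate_angle_curves",
    "forward_kinematics",
    "apply_artifacts",
    "make_pivot_trial",
    "make_static_trial",
    "make_dynamic_trial",
    "generate_study",
    "default_marker_config",
]

# cosine-series coefficients per rotation: value(phase) = sum_k c[k] cos(2*pi*k*phase)
GAIT_TEMPLATES: dict[str, tuple[float, ...]] = {
    "pelvis_tilt": (10.0, 0.0, 1.5),
    "pelvis_obliquity": (0.0, 2.5),
    "pelvis_rotation": (0.0, 5.0),
    "hip_flexion": (5.0, 25.0),
    "hip_adduction": (0.0, 4.0),
    "hip_rotation": (0.0, 3.0),
    "knee_flexion": (32.0, -30.0, -2.0),
    "knee_varus": (0.0, 1.5),
    "knee_rotation": (0.0, -1.5),   # tibia rotates internally with flexion
    "ankle_dorsiflexion": (0.0, 0.0, -8.0),
    "ankle_inversion": (0.0, 2.0),
    "ankle_adduction": (0.0, 2.5),
}

CLUSTER_LABELS = {
    "pelvis": ["PELC1", "PELC2", "PELC3"],
    "femur": ["THIC1", "THIC2", "THIC3"],
    "shank": ["SHAC1", "SHAC2", "SHAC3"],
    "foot": ["FOOC1", "FOOC2", "FOOC3"],
}
POINTER_LABELS = ["PTR1", "PTR2", "PTR3"]

#: which segment owns each registered landmark (CAST registration map)
REGISTRATION_SEGMENTS = {
    "R_ASIS": "pelvis", "L_ASIS": "pelvis", "R_PSIS": "pelvis", "L_PSIS": "pelvis",
    "R_MFE": "femur", "R_LFE": "femur",
    "R_TT": "shank", "R_FH": "shank", "R_MM": "shank", "R_LM": "shank",
    "R_CAL": "foot", "R_MT2": "foot", "R_MT5": "foot",
}

_STA_DIRECTIONS = {   # unit displacement directions of cycle-locked cluster STA
    "pelvis": np.array([1.0, 0.0, 0.0]),
    "femur": np.array([0.8, 0.0, 0.6]),
    "shank": np.array([0.6, 0.0, 0.8]),
    "foot": np.array([1.0, 0.0, 0.0]),
}
_STA_PHASES = {"pelvis": 0.0, "femur": 0.7, "shank": 1.4, "foot": 2.1}


def _rot(seq: str, *angles_deg: float) -> np.ndarray:
    R = np.eye(3)
    fns = {"x": _rx, "y": _ry, "z": _rz}
    for ax, a in zip(seq, angles_deg):
        R = R @ fns[ax](np.deg2rad(a))
    return R


@dataclass
class SyntheticSubject:
    """Rigid-segment geometry of one simulated subject (mm, segment frames).

    Landmark coordinates are fixed in their segment's anatomical frame
    (pelvis origin mid-ASIS, femur origin at the hip joint centre, shank
    origin at the knee centre, foot origin at the ankle centre with the foot
    frame shank-aligned in the neutral stance).  The femur is attached at the
    hip joint centre the Davis regression predicts from the subject's own
    anthropometrics, so the analysis model's assumption holds exactly.
    """

    subject_id: str = "S1"
    femur_length: float = 420.0
    shank_length: float = 400.0
    leg_length: float = 890.0
    inter_asis: float = 240.0
    knee_width: float = 110.0
    ankle_width: float = 90.0
    marker_radius: float = 0.0
    pelvis_height: float = 1000.0
    crosstalk_deg: float = 0.0     # thigh-wand rotation off the frontal plane

    def __post_init__(self) -> None:
        for name in ("femur_length", "shank_length", "leg_length", "inter_asis",
                     "knee_width", "ankle_width", "pelvis_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def hjc_local(self) -> np.ndarray:
        return davis_hip_joint_centre(self.leg_length, self.inter_asis,
                                      marker_radius=self.marker_radius,
                                      side="right").local

    def landmark_locals(self) -> dict[str, dict[str, np.ndarray]]:
        lf, ls = self.femur_length, self.shank_length
        kw2 = self.knee_width / 2 + self.marker_radius
        aw2 = self.ankle_width / 2 + self.marker_radius
        d2 = self.inter_asis / 2
        wand = np.array([0.0, -lf / 2, 130.0])
        if self.crosstalk_deg:
            wand = _ry(np.deg2rad(self.crosstalk_deg)) @ wand
        return {
            "pelvis": {
                "R_ASIS": np.array([0.0, 0.0, d2]),
                "L_ASIS": np.array([0.0, 0.0, -d2]),
                "R_PSIS": np.array([-140.0, 0.0, 45.0]),
                "L_PSIS": np.array([-140.0, 0.0, -45.0]),
                "SACR": np.array([-140.0, 0.0, 0.0]),
            },
            "femur": {
                "R_MFE": np.array([0.0, -lf, -55.0]),
                "R_LFE": np.array([0.0, -lf, 55.0]),
                "R_KNEE": np.array([0.0, -lf, kw2]),
                "R_THIGH_WAND": wand,
            },
            "shank": {
                "R_TT": np.array([40.0, -70.0, -10.0]),
                "R_FH": np.array([-40.0, -70.0, 10.0]),
                "R_MM": np.array([0.0, -ls, -45.0]),
                "R_LM": np.array([0.0, -ls, 45.0]),
                "R_ANKLE": np.array([0.0, -ls, aw2]),
                "R_SHANK_WAND": np.array([0.0, -ls / 2, 100.0]),
            },
            "foot": {
                "R_CAL": np.array([-85.0, -65.0, 0.0]),
                "R_MT1": np.array([140.0, -70.0, -35.0]),
                "R_MT2": np.array([150.0, -65.0, 5.0]),
                "R_MT5": np.array([125.0, -70.0, 40.0]),
                "R_HEEL": np.array([-85.0, -65.0, 0.0]),
                "R_TOE": np.array([150.0, -65.0, 5.0]),
            },
        }

    def cluster_locals(self) -> dict[str, np.ndarray]:
        """Cluster marker positions in each segment's anatomical frame."""
        triad = np.array([[0.0, 0.0, 0.0], [70.0, 15.0, 0.0], [25.0, 75.0, 10.0]])
        mounts = {
            "pelvis": (_rot("zx", 15, 10), np.array([-80.0, 20.0, 80.0])),
            "femur": (_rot("yz", 25, 10),
                      np.array([30.0, -self.femur_length / 2, 70.0])),
            "shank": (_rot("yx", -20, 8),
                      np.array([20.0, -self.shank_length / 2, 55.0])),
            "foot": (_rot("x", 12), np.array([40.0, -30.0, 0.0])),
        }
        return {seg: triad @ R.T + t for seg, (R, t) in mounts.items()}

    @property
    def pointer_reference(self) -> np.ndarray:
        return np.array([[0.0, 0.0, 0.0], [70.0, 0.0, 0.0], [0.0, 55.0, 20.0]])

    @property
    def pointer_tip(self) -> np.ndarray:
        return np.array([130.0, -20.0, 15.0])


@dataclass
class SimulationConfig:
    """Study design and perturbation dials; all SDs >= 0, seed recorded."""

    n_subjects: int = 4
    n_trials: int = 3
    rate: float = 100.0
    stride_s: float = 1.1
    stride_length_mm: float = 1250.0
    lead_s: float = 0.5
    tail_s: float = 0.3
    n_cycles: int = 1
    intertrial_sd_deg: float = 1.0
    between_subject_sd_deg: float = 3.0
    marker_noise_mm: float = 0.0
    sta_amplitude_mm: dict[str, float] = field(default_factory=dict)
    crosstalk_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1 or self.n_cycles < 1:
            raise ValueError("subject/trial/cycle counts must be >= 1")
        if min(self.intertrial_sd_deg, self.between_subject_sd_deg,
               self.marker_noise_mm) < 0:
            raise ValueError("all SDs must be >= 0")
        if any(v < 0 for v in self.sta_amplitude_mm.values()):
            raise ValueError("STA amplitudes must be >= 0")
        if self.rate <= 0 or self.stride_s <= 0:
            raise ValueError("rate and stride duration must be positive")


def _exact_sd_offsets(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """n offsets with zero mean and sample SD (n-1 denominator) exactly sd."""
    if n < 2 or sd == 0.0:
        return np.zeros(n)
    while True:
        v = rng.standard_normal(n)
        v -= v.mean()
        s = v.std(ddof=1)
        if s > 1e-12:
            return v * (sd / s)


def study_offsets(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(subject offsets (n_sub, 12), trial offsets (n_sub, n_trials, 12))."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n_rot = len(ROTATION_LABELS)
    subj = np.stack([_exact_sd_offsets(rng, config.n_subjects,
                                       config.between_subject_sd_deg)
                     for _ in range(n_rot)], axis=1)
    trial = np.stack([[_exact_sd_offsets(rng, config.n_trials,
                                         config.intertrial_sd_deg)
                       for _ in range(n_rot)]
                      for _ in range(config.n_subjects)])
    return subj, np.swapaxes(trial, 1, 2)


def evaluate_template(phase: np.ndarray) -> np.ndarray:
    """Template rotations at the given cycle phases, (len(phase), 12) degrees."""
    phase = np.asarray(phase, float)
    out = np.zeros(phase.shape + (len(ROTATION_LABELS),))
    for j, label in enumerate(ROTATION_LABELS):
        for k, c in enumerate(GAIT_TEMPLATES[label]):
            out[..., j] += c * np.cos(2 * np.pi * k * phase)
    return out


def generate_angle_curves(config: SimulationConfig, subject: int, trial: int,
                          phase: np.ndarray | None = None) -> np.ndarray:
    """Ground-truth rotation curves for one subject/trial, (len(phase), 12).

    Deterministic in (config.seed, subject, trial); the default phase grid is
    the 101-point normalised cycle.
    """
    if phase is None:
        phase = np.linspace(0.0, 1.0, 101)
    subj_off, trial_off = study_offsets(config)
    return (evaluate_template(phase)
            + subj_off[subject] + trial_off[subject, trial])


def forward_kinematics(subject: SyntheticSubject, angles: np.ndarray,
                       pelvis_translation: np.ndarray,
                       ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray],
                                  dict[str, dict[str, np.ndarray]]]:
    """Compose segment poses down the chain and emit all points in lab frame.

    Returns (segment poses {seg: (R (T,3,3), t (T,3))}, cluster marker stacks
    {seg: (T, 3, 3)}, landmark positions {seg: {name: (T, 3)}}).
    """
    ang = np.asarray(angles, float)
    if not np.all(np.isfinite(ang)):
        raise ValueError("prescribed angle curves must be finite")
    if np.any(np.abs(ang[:, [1, 4, 7, 10]]) >= 89.0):
        raise ValueError("prescribed middle Cardan angle too close to gimbal lock")
    T = ang.shape[0]
    t_pel = np.asarray(pelvis_translation, float)

    R_pel = joint_rotation_matrix("pelvis", ang[:, 0], ang[:, 1], ang[:, 2])
    R_hip = joint_rotation_matrix("hip", ang[:, 3], ang[:, 4], ang[:, 5])
    R_knee = joint_rotation_matrix("knee", ang[:, 6], ang[:, 7], ang[:, 8])
    R_ank = joint_rotation_matrix("ankle", ang[:, 9], ang[:, 10], ang[:, 11])

    hjc = subject.hjc_local
    knee_local = np.array([0.0, -subject.femur_length, 0.0])
    ankle_local = np.array([0.0, -subject.shank_length, 0.0])

    R_fem = R_pel @ R_hip
    t_fem = np.einsum("tij,j->ti", R_pel, hjc) + t_pel
    R_sha = R_fem @ R_knee
    t_sha = np.einsum("tij,j->ti", R_fem, knee_local) + t_fem
    R_foo = R_sha @ R_ank
    t_foo = np.einsum("tij,j->ti", R_sha, ankle_local) + t_sha

    poses = {"pelvis": (R_pel, t_pel), "femur": (R_fem, t_fem),
             "shank": (R_sha, t_sha), "foot": (R_foo, t_foo)}

    cluster_locals = subject.cluster_locals()
    clusters = {seg: np.einsum("tij,mj->tmi", R, cluster_locals[seg])
                + t[:, None, :] for seg, (R, t) in poses.items()}
    landmarks = {seg: {name: np.einsum("tij,j->ti", poses[seg][0], v)
                       + poses[seg][1]
                       for name, v in segland.items()}
                 for seg, segland in subject.landmark_locals().items()}
    return poses, clusters, landmarks


def _as_marker_set(label_groups: list[tuple[list[str], np.ndarray]],
                   rate: float) -> MarkerTrajectorySet:
    labels: list[str] = []
    stacks: list[np.ndarray] = []
    for labs, arr in label_groups:
        labels.extend(labs)
        stacks.append(arr if arr.ndim == 3 else arr[:, None, :])
    pos = np.concatenate(stacks, axis=1)
    return MarkerTrajectorySet(labels, pos, rate,
                               np.ones(pos.shape[:2], bool))


def apply_artifacts(mset: MarkerTrajectorySet, config: SimulationConfig,
                    phase: np.ndarray | None = None,
                    segment_labels: dict[str, list[str]] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> MarkerTrajectorySet:
    """Add measurement noise and cycle-locked soft-tissue artefact.

    Noise: i.i.d. isotropic Gaussian of SD ``marker_noise_mm`` on every valid
    sample.  STA: every marker of a segment listed in ``sta_amplitude_mm`` is
    displaced by ``A * sin(2*pi*phase + phase_lag)`` along a fixed
    segment-specific direction, emulating cluster motion relative to the bone
    locked to the gait cycle.  With zero amplitudes and zero noise the input
    is returned unchanged.
    """
    if config.marker_noise_mm == 0 and not any(config.sta_amplitude_mm.values()):
        return mset
    pos = mset.positions.copy()
    if any(config.sta_amplitude_mm.values()):
        if phase is None or segment_labels is None:
            raise ValueError("STA needs the cycle phase and segment label map")
        for seg, amp in config.sta_amplitude_mm.items():
            if amp == 0:
                continue
            wave = amp * np.sin(2 * np.pi * np.asarray(phase, float)
                                + _STA_PHASES[seg])
            direction = _STA_DIRECTIONS[seg] / np.linalg.norm(_STA_DIRECTIONS[seg])
            offset = wave[:, None] * direction
            for lb in segment_labels.get(seg, []):
                if lb in mset.labels:
                    pos[:, mset.index(lb), :] += offset
    if config.marker_noise_mm > 0:
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        pos += rng.normal(0.0, config.marker_noise_mm, pos.shape)
    pos[~mset.valid_mask] = np.nan
    return MarkerTrajectorySet(list(mset.labels), pos, mset.rate,
                               mset.valid_mask.copy())


def segment_label_map(subject: SyntheticSubject) -> dict[str, list[str]]:
    """All emitted labels per segment (cluster + skin/wand markers)."""
    lands = subject.landmark_locals()
    return {seg: CLUSTER_LABELS[seg] + sorted(lands[seg])
            for seg in CLUSTER_LABELS}


def make_pivot_trial(subject: SyntheticSubject, rate: float = 100.0,
                     n_frames: int = 200,
                     pivot_point: np.ndarray | None = None,
                     ) -> MarkerTrajectorySet:
    """Pointer markers while the pointer pivots about its stationary tip."""
    if pivot_point is None:
        pivot_point = np.array([200.0, 150.0, 950.0])
    t = np.linspace(0, 4 * np.pi, n_frames)
    Rs = np.stack([_rot("zxy", np.rad2deg(0.8 * np.sin(a)),
                        np.rad2deg(0.7 * np.cos(0.9 * a)),
                        np.rad2deg(0.5 * np.sin(1.3 * a))) for a in t])
    tip = subject.pointer_tip
    ds = pivot_point - np.einsum("tij,j->ti", Rs, tip)
    markers = np.einsum("tij,mj->tmi", Rs, subject.pointer_reference) \
        + ds[:, None, :]
    return _as_marker_set([(POINTER_LABELS, markers)], rate)


def make_static_trial(subject: SyntheticSubject, rate: float = 100.0,
                      window: int = 20,
                      ) -> tuple[MarkerTrajectorySet, dict[str, tuple[int, int]]]:
    """Neutral-pose static trial with the pointer visiting every landmark.

    Returns the marker set (clusters + skin markers + pointer) and the
    registration schedule {landmark: (first_frame, last_frame_exclusive)}.
    """
    names = list(REGISTRATION_SEGMENTS)
    T = window * len(names)
    zeros = np.zeros((T, 12))
    t_pel = np.tile(np.array([0.0, subject.pelvis_height, 0.0]), (T, 1))
    _, clusters, landmarks = forward_kinematics(subject, zeros, t_pel)

    tip = subject.pointer_tip
    ptr = np.empty((T, 3, 3))
    schedule: dict[str, tuple[int, int]] = {}
    for k, name in enumerate(names):
        seg = REGISTRATION_SEGMENTS[name]
        target = landmarks[seg][name][0]
        R = _rot("zxy", 30.0 * k, 15.0, -10.0 * k)
        d = target - R @ tip
        ptr[k * window:(k + 1) * window] = subject.pointer_reference @ R.T + d
        schedule[name] = (k * window, (k + 1) * window)

    groups: list[tuple[list[str], np.ndarray]] = []
    for seg in CLUSTER_LABELS:
        groups.append((CLUSTER_LABELS[seg], clusters[seg]))
        for name in sorted(landmarks[seg]):
            groups.append(([name], landmarks[seg][name]))
    groups.append((POINTER_LABELS, ptr))
    return _as_marker_set(groups, rate), schedule


def make_dynamic_trial(subject: SyntheticSubject, config: SimulationConfig,
                       subject_idx: int, trial_idx: int,
                       ) -> tuple[MarkerTrajectorySet, np.ndarray, list[int],
                                  np.ndarray]:
    """One walking trial.

    Returns (markers, ground-truth per-frame angles (T, 12), true foot-strike
    frames, cycle phase per frame).
    """
    rate, stride = config.rate, config.stride_s
    duration = config.lead_s + config.n_cycles * stride + config.tail_s
    T = int(round(duration * rate)) + 1
    time = np.arange(T) / rate
    phase = (time - config.lead_s) / stride
    angles = generate_angle_curves(config, subject_idx, trial_idx, phase)

    speed = config.stride_length_mm / stride
    t_pel = np.stack([
        speed * time,
        subject.pelvis_height + 12.0 * np.cos(4 * np.pi * phase),
        8.0 * np.cos(2 * np.pi * phase),
    ], axis=1)
    _, clusters, landmarks = forward_kinematics(subject, angles, t_pel)

    groups: list[tuple[list[str], np.ndarray]] = []
    for seg in CLUSTER_LABELS:
        groups.append((CLUSTER_LABELS[seg], clusters[seg]))
        for name in sorted(landmarks[seg]):
            groups.append(([name], landmarks[seg][name]))
    mset = _as_marker_set(groups, rate)

    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 13, subject_idx, trial_idx]))
    mset = apply_artifacts(mset, config, phase=phase,
                           segment_labels=segment_label_map(subject), rng=rng)
    events = [int(round((config.lead_s + k * stride) * rate))
              for k in range(config.n_cycles + 1)]
    return mset, angles, events, phase


def default_marker_config(subject: SyntheticSubject,
                          model: str = "ISB6DOF") -> MarkerSetConfig:
    anthro = {
        "leg_length_mm": subject.leg_length,
        "inter_asis_mm": subject.inter_asis,
        "marker_radius_mm": subject.marker_radius,
        "knee_width_mm": subject.knee_width,
        "ankle_width_mm": subject.ankle_width,
    }
    if model == "ISB6DOF":
        segland: dict[str, list[str]] = {}
        for name, seg in REGISTRATION_SEGMENTS.items():
            segland.setdefault(seg, []).append(name)
        return MarkerSetConfig("ISB6DOF", clusters=dict(CLUSTER_LABELS),
                               landmarks=segland, anthropometrics=anthro)
    return MarkerSetConfig("HH", clusters={}, landmarks={}, anthropometrics=anthro)


def generate_study(config: SimulationConfig, outdir, fmt: str = "csv") -> dict:
    """Write a complete synthetic study to disk and return its manifest.

    Per subject: one static trial (with pointer registration schedule), one
    pointer pivot trial, and ``n_trials`` dynamic trials, each beside its
    ground-truth angle file.  The manifest (YAML) records the seed, the full
    configuration, anthropometrics, file names, registration schedule and
    true event frames.
    """
    if fmt not in ("csv", "c3d"):
        raise ValueError("fmt must be 'csv' or 'c3d'")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "config": {**asdict(config)},
                      "rate": config.rate, "format": fmt, "subjects": {}}
    for i in range(config.n_subjects):
        sid = f"S{i + 1}"
        subject = SyntheticSubject(subject_id=sid,
                                   crosstalk_deg=config.crosstalk_deg)
        static, schedule = make_static_trial(subject, config.rate)
        pivot = make_pivot_trial(subject, config.rate)
        static_file = f"static_{sid}.{fmt}"
        pivot_file = f"pivot_{sid}.{fmt}"
        write_trial(static, out / static_file)
        write_trial(pivot, out / pivot_file)
        sub_entry = {
            "anthropometrics": {
                "leg_length_mm": subject.leg_length,
                "inter_asis_mm": subject.inter_asis,
                "marker_radius_mm": subject.marker_radius,
                "knee_width_mm": subject.knee_width,
                "ankle_width_mm": subject.ankle_width,
            },
            "static": static_file, "pivot": pivot_file,
            "schedule": {k: list(v) for k, v in schedule.items()},
            "trials": [],
        }
        for j in range(config.n_trials):
            mset, angles, events, _ = make_dynamic_trial(subject, config, i, j)
            trial_file = f"trial_{sid}_T{j + 1}.{fmt}"
            gt_file = f"gt_{sid}_T{j + 1}.csv"
            write_trial(mset, out / trial_file)
            write_angle_curves(angles, out / gt_file)
            sub_entry["trials"].append({"file": trial_file, "truth": gt_file,
                                        "events": events})
        manifest["subjects"][sid] = sub_entry
    default_marker_config(SyntheticSubject()).to_yaml(out / "markerset.yaml")
    manifest["markerset"] = "markerset.yaml"
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
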