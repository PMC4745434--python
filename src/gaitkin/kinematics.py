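"""Cardan joint angles from segment anatomical frames.

All segment frames follow the ISB polarity (X anterior, Y superior, Z to the
subject's right).  The relative orientation of a distal segment in its proximal
segment, ``R_rel = R_prox^T R_dist``, is decomposed in the intrinsic Z-X-Y
Cardan sequence

    R_rel = Rz(alpha) @ Rx(beta) @ Ry(gamma)

so that alpha is the rotation about the proximal mediolateral axis
(flexion/extension), beta about the floating anteroposterior axis
(ab/adduction), and gamma about the distal longitudinal axis
(internal/external rotation) — the joint-coordinate-system-equivalent
convention.  Pelvis angles use the same sequence against the laboratory frame
(tilt, obliquity, rotation).

Sign conventions for the right lower limb (see ``SIGN_TABLE``): flexion,
adduction/varus and internal rotation are positive; knee flexion is the one
label whose clinical positive direction is opposite the raw Z rotation, so its
sign multiplier is -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rigid_body import Pose, PoseSeries

__all__ = [
    "ROTATION_LABELS",
    "SIGN_TABLE",
    "CARDAN_SEQUENCE",
    "AngleTimeSeries",
    "GaitCycleAngles",
    "cardan_compose",
    "cardan_decompose",
    "relative_rotation",
    "joint_rotation_matrix",
    "compute_joint_angles",
]

#: The 12 reported rotations, in conventional report order
#: (pelvis, hip, knee, ankle; sagittal, frontal, transverse within each).
ROTATION_LABELS: tuple[str, ...] = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "knee_varus",
    "knee_rotation",
    "ankle_dorsiflexion",
    "ankle_inversion",
    "ankle_adduction",
)

#: joint -> (proximal segment, distal segment); pelvis is measured against lab.
JOINT_SEGMENTS = {
    "pelvis": (None, "pelvis"),
    "hip": ("pelvis", "femur"),
    "knee": ("femur", "shank"),
    "ankle": ("shank", "foot"),
}

CARDAN_SEQUENCE = "ZXY"

#: multiplier turning raw Z-X-Y Cardan angles into clinical angles (right limb)
SIGN_TABLE: dict[str, float] = {label: 1.0 for label in ROTATION_LABELS}
SIGN_TABLE["knee_flexion"] = -1.0   # knee flexion carries the shank posteriorly

GIMBAL_LIMIT_DEG = 89.9


def _rz(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack([np.stack([c, -s, z], -1),
                     np.stack([s, c, z], -1),
                     np.stack([z, z, o], -1)], -2)


def _rx(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack([np.stack([o, z, z], -1),
                     np.stack([z, c, -s], -1),
                     np.stack([z, s, c], -1)], -2)


def _ry(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack([np.stack([c, z, s], -1),
                     np.stack([z, o, z], -1),
                     np.stack([-s, z, c], -1)], -2)


def cardan_compose(alpha: float | np.ndarray,
                   beta: float | np.ndarray,
                   gamma: float | np.ndarray,
                   degrees: bool = True) -> np.ndarray:
    """Rotation matrix (or stack) from Z-X-Y Cardan angles."""
    a = np.asarray(alpha, float)
    b = np.asarray(beta, float)
    g = np.asarray(gamma, float)
    if degrees:
        a, b, g = np.deg2rad(a), np.deg2rad(b), np.deg2rad(g)
    return _rz(a) @ _rx(b) @ _ry(g)


def cardan_decompose(rotation: np.ndarray, degrees: bool = True,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-X-Y Cardan angles of a rotation matrix (or stack of matrices).

    Returns (alpha, beta, gamma, gimbal_flag).  The middle angle beta is taken
    in (-90 deg, 90 deg].  Near gimbal lock (|beta| > 89.9 deg) only the sum or
    difference of alpha and gamma is observable; by convention gamma is set to
    0, alpha absorbs the remaining rotation and the sample is flagged.
    """
    R = np.asarray(rotation, float)
    sb = np.clip(R[..., 2, 1], -1.0, 1.0)
    beta = np.arcsin(sb)
    gimbal = np.abs(np.rad2deg(beta)) > GIMBAL_LIMIT_DEG
    alpha = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
    gamma = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
    if np.any(gimbal):
        # R reduces to Rz(alpha -/+ gamma)·Rx(±90°); take gamma := 0
        a_lock = np.arctan2(R[..., 1, 0], R[..., 0, 0])
        alpha = np.where(gimbal, a_lock, alpha)
        gamma = np.where(gimbal, 0.0, gamma)
    if degrees:
        alpha, beta, gamma = map(np.rad2deg, (alpha, beta, gamma))
    return alpha, beta, gamma, gimbal


def relative_rotation(proximal: Pose | np.ndarray,
                      distal: Pose | np.ndarray) -> np.ndarray:
    """Orientation of the distal frame in the proximal frame, R_prox^T R_dist."""
    Rp = proximal.rotation if isinstance(proximal, Pose) else np.asarray(proximal, float)
    Rd = distal.rotation if isinstance(distal, Pose) else np.asarray(distal, float)
    return np.swapaxes(Rp, -1, -2) @ Rd


def joint_rotation_matrix(joint: str, flexion: np.ndarray, adduction: np.ndarray,
                          rotation: np.ndarray) -> np.ndarray:
    """Compose the relative rotation of a joint from its clinical angles (deg).

    Inverse of the decomposition used by :func:`compute_joint_angles`; the
    synthetic gait generator drives forward kinematics through this exact map
    so prescribed and recovered angles share one convention.
    """
    labels = [lab for lab in ROTATION_LABELS if lab.startswith(joint)]
    s = [SIGN_TABLE[lab] for lab in labels]
    return cardan_compose(s[0] * np.asarray(flexion, float),
                          s[1] * np.asarray(adduction, float),
                          s[2] * np.asarray(rotation, float))


@dataclass
class AngleTimeSeries:
    """The 12 clinical rotations sampled at the capture rate (degrees)."""

    values: np.ndarray                 # (T, 12)
    rate: float                        # Hz
    valid: np.ndarray                  # (T,)
    labels: tuple[str, ...] = ROTATION_LABELS
    gimbal: np.ndarray | None = None   # (T, 12) bool warning flags

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.valid = np.asarray(self.valid, bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("values must be (T, n_labels)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def curve(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


@dataclass
class GaitCycleAngles:
    """One gait cycle: 12 rotations time-normalised to 101 samples."""

    values: np.ndarray                     # (101, 12) degrees
    labels: tuple[str, ...] = ROTATION_LABELS
    trial_id: str = ""
    cycle_index: int = 0
    events: tuple[int, int] = (0, 0)       # start/end foot-strike frames

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (101, len(self.labels)):
            raise ValueError(
                f"expected (101, {len(self.labels)}) samples, got {self.values.shape}")
        if self.events[1] < self.events[0]:
            raise ValueError("event frames must be increasing")

    def curve(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


def _unwrap_deg(x: np.ndarray) -> np.ndarray:
    return np.rad2deg(np.unwrap(np.deg2rad(x), axis=0))


def compute_joint_angles(frames: dict[str, PoseSeries],
                         lab_frame: Pose | None = None,
                         rate: float = 100.0,
                         unwrap: bool = True) -> AngleTimeSeries:
    """Clinical joint angles from per-frame segment anatomical poses.

    Pelvis angles are measured against the laboratory frame; hip, knee and
    ankle against the proximal segment.  Each relative rotation is decomposed
    in the Z-X-Y sequence and mapped through ``SIGN_TABLE``.
    """
    for seg in ("pelvis", "femur", "shank", "foot"):
        if seg not in frames:
            raise ValueError(f"missing segment frames: {seg!r}")
    T = len(frames["pelvis"])
    lab = Pose.identity() if lab_frame is None else lab_frame
    values = np.full((T, 12), np.nan)
    gimbal = np.zeros((T, 12), bool)
    valid = np.ones(T, bool)
    col = 0
    for joint, (prox, dist) in JOINT_SEGMENTS.items():
        dseries = frames[dist]
        Rd = dseries.rotations
        if prox is None:
            Rp = np.broadcast_to(lab.rotation, (T, 3, 3))
            ok = dseries.valid
        else:
            pseries = frames[prox]
            Rp = pseries.rotations
            ok = pseries.valid & dseries.valid
        rel = relative_rotation(np.where(ok[:, None, None], Rp, np.eye(3)),
                                np.where(ok[:, None, None], Rd, np.eye(3)))
        a, b, g, gl = cardan_decompose(rel)
        labels = [lab_ for lab_ in ROTATION_LABELS if lab_.startswith(joint)]
        raw = np.stack([a, b, g], axis=1)
        for k, lab_ in enumerate(labels):
            values[:, col + k] = np.where(ok, SIGN_TABLE[lab_] * raw[:, k], np.nan)
            gimbal[:, col + k] = gl & ok
        valid &= ok
        col += 3
    if unwrap and valid.all():
        values = _unwrap_deg(values)
    return AngleTimeSeries(values, rate, valid, gimbal=gimbal)
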