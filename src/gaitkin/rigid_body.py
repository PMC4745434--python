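"""Rigid-body pose estimation, pointer (stylus) calibration and virtual markers.

A marker *cluster* is a set of >= 3 noncollinear markers on a rigid base attached
to a body segment.  Its pose in the laboratory is estimated per frame by
least-squares orthogonal Procrustes fitting against a reference geometry taken
from the static trial.  Anatomical landmarks are registered once, with a tracked
pointer, as constant vectors in the cluster technical frame and reconstructed
during movement as *virtual markers* from the cluster's current transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pose",
    "PoseSeries",
    "PointerModel",
    "AnatomicalCalibration",
    "GeometryError",
    "CalibrationError",
    "fit_rigid_transform",
    "fit_pose_series",
    "pivot_calibrate",
    "register_landmark",
    "reconstruct_virtual_marker",
]

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Degenerate marker geometry (collinear / coincident points)."""


class CalibrationError(RuntimeError):
    """A calibration step could not be completed from the supplied data."""


@dataclass(frozen=True)
class Pose:
    """Rigid transform ``x_lab = rotation @ x_local + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("Pose requires a 3x3 rotation and a 3-vector translation")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map local points (..., 3) into the parent frame."""
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)


@dataclass
class PoseSeries:
    """Per-frame poses of one frame (technical or anatomical) in its parent.

    ``valid`` marks frames where the pose could actually be estimated; invalid
    frames carry NaN and must never be silently used downstream.
    """

    rotations: np.ndarray   # (T, 3, 3)
    translations: np.ndarray  # (T, 3)
    valid: np.ndarray       # (T,) bool
    residual_rms: np.ndarray | None = None  # (T,) mm, for fitted poses

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, float)
        self.translations = np.asarray(self.translations, float)
        self.valid = np.asarray(self.valid, bool)
        T = self.rotations.shape[0]
        if self.rotations.shape != (T, 3, 3) or self.translations.shape != (T, 3):
            raise ValueError("inconsistent PoseSeries shapes")
        if self.valid.shape != (T,):
            raise ValueError("valid mask length mismatch")

    def __len__(self) -> int:
        return self.rotations.shape[0]

    def pose(self, i: int) -> Pose:
        if not self.valid[i]:
            raise CalibrationError(f"pose invalid at frame {i}")
        return Pose(self.rotations[i], self.translations[i])

    def apply(self, local: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Reconstruct a constant local vector in the parent frame, per frame.

        Returns (positions (T,3), valid (T,)); invalid frames are NaN.
        """
        local = np.asarray(local, float)
        out = np.einsum("tij,j->ti", self.rotations, local) + self.translations
        out[~self.valid] = np.nan
        return out, self.valid.copy()

    @staticmethod
    def identity(n_frames: int) -> "PoseSeries":
        return PoseSeries(np.broadcast_to(np.eye(3), (n_frames, 3, 3)).copy(),
                          np.zeros((n_frames, 3)), np.ones(n_frames, bool))


@dataclass
class PointerModel:
    """Calibrated pointer: tip offset in the pointer technical frame."""

    marker_labels: tuple[str, ...]
    tip_offset: np.ndarray          # (3,) mm, pointer frame
    residual_rms: float             # mm, pivot-fit residual
    reference_points: np.ndarray    # (n, 3) pointer cluster reference geometry

    def __post_init__(self) -> None:
        self.tip_offset = np.asarray(self.tip_offset, float)
        if self.residual_rms < 0:
            raise ValueError("residual RMS must be >= 0")


@dataclass
class AnatomicalCalibration:
    """Per-segment landmark vectors in the segment's cluster technical frame.

    ``reference_geometry`` stores, per segment, the static-trial mean marker
    positions that define the technical frame (the cluster pose is identity in
    the static trial by construction).
    """

    landmarks: dict[str, dict[str, np.ndarray]]        # segment -> name -> (3,)
    reference_geometry: dict[str, np.ndarray]          # segment -> (n, 3)
    residuals: dict[str, float] = field(default_factory=dict)   # landmark -> mm

    def local_vector(self, segment: str, name: str) -> np.ndarray:
        try:
            return self.landmarks[segment][name]
        except KeyError:
            raise CalibrationError(
                f"landmark {name!r} is not calibrated for segment {segment!r}")


def fit_rigid_transform(reference_points: np.ndarray,
                        observed_points: np.ndarray,
                        weights: np.ndarray | None = None,
                        ) -> tuple[Pose, float]:
    """Least-squares rigid transform mapping reference onto observed points.

    SVD-based orthogonal Procrustes solution (Soderkvist-Wedin) with a
    reflection guard: the smallest singular direction is negated when the
    unconstrained optimum is a reflection, so the result is always a proper
    rotation.  Returns the pose and the weighted residual RMS in mm.
    """
    P = np.asarray(reference_points, float)
    Q = np.asarray(observed_points, float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape != Q.shape:
        raise ValueError("reference and observed must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    wn = w / w.sum()
    cp = wn @ P
    cq = wn @ Q
    Pc = P - cp
    Qc = Q - cq
    # collinearity check on the centred reference spread
    sv = np.linalg.svd(Pc * np.sqrt(wn)[:, None], compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError("reference points are (near-)collinear")
    H = (Pc * wn[:, None]).T @ Qc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    res = Q - (P @ R.T + t)
    rms = float(np.sqrt(np.sum(wn[:, None] * res**2)))
    return Pose(R, t), rms


def fit_pose_series(reference_points: np.ndarray,
                    observed: np.ndarray,
                    observed_valid: np.ndarray | None = None,
                    ) -> PoseSeries:
    """Fit the cluster pose at every frame of an (T, n, 3) observation stack.

    Frames where any cluster marker is invalid are flagged invalid rather than
    fitted from partial data.
    """
    obs = np.asarray(observed, float)
    T, n, _ = obs.shape
    if observed_valid is None:
        ok = np.all(np.isfinite(obs), axis=(1, 2))
    else:
        ok = np.all(np.asarray(observed_valid, bool), axis=1)
        ok &= np.all(np.isfinite(np.where(ok[:, None, None], obs, 0.0)), axis=(1, 2))
    Rs = np.full((T, 3, 3), np.nan)
    ts = np.full((T, 3), np.nan)
    rms = np.full(T, np.nan)
    for i in np.flatnonzero(ok):
        pose, r = fit_rigid_transform(reference_points, obs[i])
        Rs[i] = pose.rotation
        ts[i] = pose.translation
        rms[i] = r
    return PoseSeries(Rs, ts, ok, rms)


def pivot_calibrate(pointer_poses: list[Pose] | PoseSeries,
                    marker_labels: tuple[str, ...] = (),
                    reference_points: np.ndarray | None = None,
                    ) -> PointerModel:
    """Solve tip offset (pointer frame) and pivot point (lab) simultaneously.

    While the pointer pivots about its stationary tip, every pose satisfies
    ``R_i p_tip + d_i = p_pivot``.  Stacking all frames gives the linear system
    ``[R_i  -I] [p_tip; p_pivot] = -d_i`` solved in least squares.  Pure
    translations leave the tip offset unobservable and raise a rank error.
    """
    if isinstance(pointer_poses, PoseSeries):
        idx = np.flatnonzero(pointer_poses.valid)
        Rs = pointer_poses.rotations[idx]
        ds = pointer_poses.translations[idx]
    else:
        Rs = np.stack([p.rotation for p in pointer_poses])
        ds = np.stack([p.translation for p in pointer_poses])
    m = Rs.shape[0]
    if m < 10:
        raise CalibrationError(f"pivot calibration needs >= 10 poses, got {m}")
    A = np.zeros((3 * m, 6))
    A[:, :3] = Rs.reshape(3 * m, 3)
    A[:, 3:] = np.tile(-np.eye(3), (m, 1))
    b = -ds.reshape(3 * m)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-6 * sv[0]:
        raise CalibrationError(
            "insufficient rotational diversity: tip offset unobservable")
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    rms = float(np.sqrt(np.mean(np.sum((A @ x - b).reshape(m, 3) ** 2, axis=1))))
    return PointerModel(tuple(marker_labels), x[:3], rms,
                        np.empty((0, 3)) if reference_points is None
                        else np.asarray(reference_points, float))


def register_landmark(pointer: PointerModel,
                      pointer_poses: PoseSeries | Pose,
                      cluster_poses: PoseSeries | Pose,
                      ) -> tuple[np.ndarray, float]:
    """Express the pointer tip in a cluster's technical frame.

    Averages over all frames where both poses are valid (static-trial window);
    returns the local vector and the RMS scatter (mm) of per-frame solutions
    about their mean.
    """
    if isinstance(pointer_poses, Pose):
        pointer_poses = PoseSeries(pointer_poses.rotation[None],
                                   pointer_poses.translation[None],
                                   np.array([True]))
    if isinstance(cluster_poses, Pose):
        cluster_poses = PoseSeries(cluster_poses.rotation[None],
                                   cluster_poses.translation[None],
                                   np.array([True]))
    if len(pointer_poses) != len(cluster_poses):
        raise CalibrationError("pointer and cluster pose series length mismatch")
    ok = pointer_poses.valid & cluster_poses.valid
    if not ok.any():
        raise CalibrationError("no frame with both pointer and cluster visible")
    tip_lab, _ = pointer_poses.apply(pointer.tip_offset)
    Rc = cluster_poses.rotations[ok]
    dc = cluster_poses.translations[ok]
    local = np.einsum("tji,tj->ti", Rc, tip_lab[ok] - dc)  # R^T (tip - d)
    mean = local.mean(axis=0)
    scatter = float(np.sqrt(np.mean(np.sum((local - mean) ** 2, axis=1))))
    return mean, scatter


def reconstruct_virtual_marker(local_vector: np.ndarray,
                               cluster_poses: PoseSeries | Pose,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Virtual marker in lab coordinates from a stored local vector.

    ``p_lab(t) = R(t) @ p_local + d(t)``; frames with an invalid cluster pose
    come back NaN with ``valid`` False — gaps are never fabricated.
    """
    if isinstance(cluster_poses, Pose):
        return cluster_poses.apply(local_vector), np.array([True])
    return cluster_poses.apply(np.asarray(local_vector, float))
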