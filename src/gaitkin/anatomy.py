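"""Segment anatomical coordinate frames for the cluster (ISB 6DOF) and Helen
Hayes protocols, plus the Davis/Newington hip-joint-centre regression.

Axis convention (every segment, right limb): X anterior, Y superior, Z to the
subject's right; all frames right-handed with det +1.

Frame recipes
-------------
pelvis : origin mid-ASIS; Z along the inter-ASIS line (left->right); X in the
         plane spanned by the ASISs and the mid-PSIS (or sacrum), anterior.
femur  : origin at the hip joint centre (HJC); Y from the mid-epicondyle point
         up to the HJC; Z toward the lateral epicondyle.
shank  : origin at the inter-malleolar point; Y toward the midpoint of the
         tibial tuberosity and fibular head (shank-owned proximal landmarks,
         so shank kinematics are independent of the thigh cluster); Z toward
         the lateral malleolus.
foot   : copied from the shank anatomical frame during a neutral static trial
         and rigidly attached to the foot technical frame thereafter, so the
         neutral ankle reads (0, 0, 0) by construction.

The Helen Hayes thigh and shank frames use skin markers plus manually aligned
wands: the wand defines the segment frontal plane, and the knee/ankle joint
centres are found with the chord construction (joint centre in the wand plane,
at half segment width plus marker radius from the lateral marker, with the
centre-to-lateral-marker line perpendicular to the long axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigid_body import GeometryError, Pose, PoseSeries

__all__ = [
    "LANDMARK_VOCABULARY",
    "LandmarkSet",
    "HipJointCentre",
    "davis_hip_joint_centre",
    "pelvis_frame",
    "femur_frame_isb",
    "shank_frame_isb",
    "build_isb_frames",
    "build_hh_frames",
    "chord_joint_centre",
]

LANDMARK_VOCABULARY = frozenset({
    "R_ASIS", "L_ASIS", "R_PSIS", "L_PSIS", "SACR",
    "R_GT", "R_MFE", "R_LFE",
    "R_TT", "R_FH", "R_MM", "R_LM",
    "R_CAL", "R_MT1", "R_MT2", "R_MT5",
    "R_THIGH_WAND", "R_SHANK_WAND", "R_KNEE", "R_ANKLE", "R_HEEL", "R_TOE",
})

ISB_REQUIRED = {
    "pelvis": ("R_ASIS", "L_ASIS", "R_PSIS", "L_PSIS"),
    "femur": ("R_MFE", "R_LFE"),
    "shank": ("R_TT", "R_FH", "R_MM", "R_LM"),
    "foot": ("R_CAL", "R_MT2", "R_MT5"),
}

HH_REQUIRED = ("R_ASIS", "L_ASIS", "SACR", "R_THIGH_WAND", "R_KNEE",
               "R_SHANK_WAND", "R_ANKLE", "R_HEEL", "R_TOE")


class MissingLandmarkError(KeyError):
    pass


@dataclass
class LandmarkSet:
    """Lab-frame landmark positions per frame (mm), with validity."""

    positions: dict[str, np.ndarray]     # name -> (T, 3); NaN where invalid
    valid: dict[str, np.ndarray]         # name -> (T,)

    def __post_init__(self) -> None:
        unknown = set(self.positions) - LANDMARK_VOCABULARY
        if unknown:
            raise ValueError(f"unrecognised landmark names: {sorted(unknown)}")
        lengths = {v.shape[0] for v in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError("landmark series have unequal frame counts")

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    def get(self, name: str, context: str = "") -> np.ndarray:
        if name not in self.positions:
            where = f" (required for {context})" if context else ""
            raise MissingLandmarkError(f"missing landmark {name!r}{where}")
        return self.positions[name]

    def frames_valid(self, names: tuple[str, ...]) -> np.ndarray:
        ok = np.ones(self.n_frames, bool)
        for n in names:
            ok &= self.valid.get(n, np.zeros(self.n_frames, bool))
        return ok

    def transformed(self, pose: Pose) -> "LandmarkSet":
        return LandmarkSet({k: pose.apply(v) for k, v in self.positions.items()},
                           {k: v.copy() for k, v in self.valid.items()})

    @classmethod
    def single(cls, points: dict[str, np.ndarray]) -> "LandmarkSet":
        return cls({k: np.asarray(v, float)[None, :] for k, v in points.items()},
                   {k: np.array([True]) for k in points})


@dataclass(frozen=True)
class HipJointCentre:
    """HJC position in the pelvis anatomical frame (mm)."""

    local: np.ndarray
    side: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "local", np.asarray(self.local, float))
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


# Newington/Davis regression constants (from the gait model literature):
# C = 0.115 * leg_length - 15.3 mm, theta = 28.4 deg, beta = 18 deg, and the
# ASIS-to-greater-trochanter distance default 0.1288 * leg_length - 48.56 mm.
_DAVIS_THETA = np.deg2rad(28.4)
_DAVIS_BETA = np.deg2rad(18.0)


def davis_hip_joint_centre(leg_length: float, inter_asis: float,
                           asis_trochanter_offset: float | None = None,
                           marker_radius: float = 0.0,
                           side: str = "right") -> HipJointCentre:
    """Hip joint centre in the pelvis anatomical frame via the Davis regression.

    All inputs in mm.  ``asis_trochanter_offset`` defaults to the regression's
    own estimate from leg length.  The returned vector is expressed in the ISB
    pelvis frame (origin mid-ASIS, X anterior, Y up, Z right): posterior and
    inferior to the origin, lateral toward the requested side.
    """
    if leg_length <= 0 or inter_asis <= 0:
        raise ValueError("anthropometrics must be strictly positive")
    if marker_radius < 0:
        raise ValueError("marker radius must be >= 0")
    if asis_trochanter_offset is None:
        asis_trochanter_offset = 0.1288 * leg_length - 48.56
    if asis_trochanter_offset <= 0:
        raise ValueError("ASIS-trochanter offset must be strictly positive")
    C = 0.115 * leg_length - 15.3
    ct, st = np.cos(_DAVIS_THETA), np.sin(_DAVIS_THETA)
    cb, sb = np.cos(_DAVIS_BETA), np.sin(_DAVIS_BETA)
    xd = asis_trochanter_offset + marker_radius
    x = C * ct * sb - xd * cb                       # anterior (negative)
    y = -C * ct * cb - xd * sb                      # superior (negative)
    z = inter_asis / 2.0 - C * st                   # lateral magnitude
    sign = 1.0 if side == "right" else -1.0
    return HipJointCentre(np.array([x, y, sign * z]), side)


# ---------------------------------------------------------------------------
# frame construction helpers

def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-9):
        raise GeometryError(f"degenerate geometry while building {what}")
    return v / n


def _frames_from_axes(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                      origin: np.ndarray, valid: np.ndarray) -> PoseSeries:
    R = np.stack([x, y, z], axis=-1)   # columns are the axes
    R = np.where(valid[:, None, None], R, np.nan)
    o = np.where(valid[:, None], origin, np.nan)
    return PoseSeries(R, o, valid)


def pelvis_frame(r_asis: np.ndarray, l_asis: np.ndarray,
                 posterior_point: np.ndarray, valid: np.ndarray) -> PoseSeries:
    """Pelvis anatomical frame; posterior_point is mid-PSIS or the sacrum."""
    origin = 0.5 * (r_asis + l_asis)
    z = _unit(r_asis - l_asis, "pelvis Z (inter-ASIS line)")
    v = origin - posterior_point
    x = v - np.sum(v * z, -1, keepdims=True) * z
    x = _unit(x, "pelvis X (ASIS/posterior plane)")
    y = np.cross(z, x)
    return _frames_from_axes(x, y, z, origin, valid)


def femur_frame_isb(hjc_lab: np.ndarray, mfe: np.ndarray, lfe: np.ndarray,
                    valid: np.ndarray) -> PoseSeries:
    mid_ep = 0.5 * (mfe + lfe)
    y = _unit(hjc_lab - mid_ep, "femur Y (HJC-epicondyle axis)")
    z_t = lfe - mfe
    x = _unit(np.cross(y, z_t), "femur X (epicondyle plane)")
    z = np.cross(x, y)
    return _frames_from_axes(x, y, z, hjc_lab, valid)


def shank_frame_isb(tt: np.ndarray, fh: np.ndarray, mm: np.ndarray,
                    lm: np.ndarray, valid: np.ndarray) -> PoseSeries:
    origin = 0.5 * (mm + lm)
    proximal = 0.5 * (tt + fh)
    y = _unit(proximal - origin, "shank Y (long axis)")
    z_t = lm - mm
    x = _unit(np.cross(y, z_t), "shank X (malleolar plane)")
    z = np.cross(x, y)
    return _frames_from_axes(x, y, z, origin, valid)


def technical_frame_series(landmarks: LandmarkSet, names: tuple[str, ...],
                           reference: np.ndarray) -> PoseSeries:
    """Least-squares pose of a landmark triad against a reference geometry."""
    from .rigid_body import fit_pose_series

    obs = np.stack([landmarks.get(n) for n in names], axis=1)
    ok = landmarks.frames_valid(names)
    return fit_pose_series(reference, obs, np.repeat(ok[:, None], len(names), 1))


def build_isb_frames(landmarks: LandmarkSet, hjc: HipJointCentre,
                     neutral_reference: LandmarkSet | None = None,
                     foot_technical: PoseSeries | None = None,
                     neutral_shank_pose: Pose | None = None,
                     ) -> dict[str, PoseSeries]:
    """ISB anatomical frames for pelvis, femur, shank and foot.

    The foot needs a neutral static reference: either ``neutral_reference``
    (a one-frame LandmarkSet of the static trial, from which foot landmark
    triads act as the technical frame) or an explicit ``foot_technical``
    PoseSeries plus the shank anatomical pose at the neutral instant.
    """
    for seg, names in ISB_REQUIRED.items():
        if seg == "foot" and (foot_technical is not None or
                              neutral_reference is None):
            continue
        for n in names:
            landmarks.get(n, context=f"{seg} frame")

    ok_p = landmarks.frames_valid(ISB_REQUIRED["pelvis"])
    pelvis = pelvis_frame(landmarks.get("R_ASIS"), landmarks.get("L_ASIS"),
                          0.5 * (landmarks.get("R_PSIS") + landmarks.get("L_PSIS")),
                          ok_p)
    hjc_lab, _ = pelvis.apply(hjc.local)
    ok_f = ok_p & landmarks.frames_valid(ISB_REQUIRED["femur"])
    femur = femur_frame_isb(hjc_lab, landmarks.get("R_MFE"),
                            landmarks.get("R_LFE"), ok_f)
    ok_s = landmarks.frames_valid(ISB_REQUIRED["shank"])
    shank = shank_frame_isb(landmarks.get("R_TT"), landmarks.get("R_FH"),
                            landmarks.get("R_MM"), landmarks.get("R_LM"), ok_s)

    if foot_technical is None:
        if neutral_reference is None:
            raise ValueError("the foot frame requires a neutral static reference")
        triad = ISB_REQUIRED["foot"]
        ref = np.stack([neutral_reference.get(n)[0] for n in triad])
        foot_technical = technical_frame_series(landmarks, triad, ref)
        neutral_frames = build_isb_frames(
            neutral_reference, hjc,
            foot_technical=PoseSeries.identity(1),
            neutral_shank_pose=Pose.identity())
        neutral_shank_pose = neutral_frames["shank"].pose(0)
    if neutral_shank_pose is None:
        raise ValueError("neutral shank pose required with explicit foot technical frames")

    # foot anatomical = foot technical(t) ∘ [foot technical(static)]^-1 ∘ shank
    # anatomical(static); the static technical pose is identity by construction.
    T = len(foot_technical)
    Rf = foot_technical.rotations @ neutral_shank_pose.rotation
    tf = (np.einsum("tij,j->ti", foot_technical.rotations,
                    neutral_shank_pose.translation) + foot_technical.translations)
    foot = PoseSeries(Rf, tf, foot_technical.valid.copy())
    assert len(foot) == T
    return {"pelvis": pelvis, "femur": femur, "shank": shank, "foot": foot}


def chord_joint_centre(proximal: np.ndarray, lateral: np.ndarray,
                       wand: np.ndarray, offset: float) -> np.ndarray:
    """Joint centre by the chord construction (per frame).

    The centre lies in the plane through (proximal, lateral, wand), at
    ``offset`` mm from the lateral marker, with the centre->lateral segment
    perpendicular to the centre->proximal line; of the two in-plane solutions
    the one on the opposite side of the wand (medial) is returned.
    """
    d = proximal - lateral
    L = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(L[np.isfinite(L)] <= offset):
        raise GeometryError("chord offset exceeds proximal-lateral distance")
    e1 = d / L
    n = np.cross(d, wand - lateral)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn[np.isfinite(nn)] < 1e-9 * L[np.isfinite(L)]):
        raise GeometryError("wand is collinear with the segment axis")
    n = n / nn
    e2 = np.cross(n, e1)
    u = offset**2 / L[..., 0]
    v = np.sqrt(np.maximum(offset**2 - u**2, 0.0))
    side = np.sign(np.sum((wand - lateral) * e2, axis=-1))
    side = np.where(side == 0, 1.0, side)
    return lateral + u[..., None] * e1 - (side * v)[..., None] * e2


def build_hh_frames(landmarks: LandmarkSet, hjc: HipJointCentre,
                    knee_width: float, ankle_width: float,
                    marker_radius: float = 0.0) -> dict[str, PoseSeries]:
    """Helen Hayes (Davis-style) frames from skin markers and aligned wands."""
    for n in HH_REQUIRED:
        landmarks.get(n, context="Helen Hayes marker set")
    ok_p = landmarks.frames_valid(("R_ASIS", "L_ASIS", "SACR"))
    pelvis = pelvis_frame(landmarks.get("R_ASIS"), landmarks.get("L_ASIS"),
                          landmarks.get("SACR"), ok_p)
    hjc_lab, _ = pelvis.apply(hjc.local)

    lknee = landmarks.get("R_KNEE", "thigh wand plane")
    twand = landmarks.get("R_THIGH_WAND", "thigh wand plane")
    kjc = chord_joint_centre(hjc_lab, lknee, twand, knee_width / 2 + marker_radius)
    ok_t = ok_p & landmarks.frames_valid(("R_KNEE", "R_THIGH_WAND"))
    y_t = _unit(hjc_lab - kjc, "thigh Y")
    z_t = _unit(lknee - kjc, "thigh Z")
    x_t = np.cross(y_t, z_t)
    femur = _frames_from_axes(x_t, y_t, z_t, hjc_lab, ok_t)

    lank = landmarks.get("R_ANKLE", "shank wand plane")
    swand = landmarks.get("R_SHANK_WAND", "shank wand plane")
    ajc = chord_joint_centre(kjc, lank, swand, ankle_width / 2 + marker_radius)
    ok_s = ok_t & landmarks.frames_valid(("R_ANKLE", "R_SHANK_WAND"))
    y_s = _unit(kjc - ajc, "shank Y")
    z_s = _unit(lank - ajc, "shank Z")
    x_s = np.cross(y_s, z_s)
    shank = _frames_from_axes(x_s, y_s, z_s, ajc, ok_s)

    heel = landmarks.get("R_HEEL", "foot line")
    toe = landmarks.get("R_TOE", "foot line")
    ok_f = ok_s & landmarks.frames_valid(("R_HEEL", "R_TOE"))
    x_f = _unit(toe - heel, "foot X")
    y_f = _unit(np.cross(z_s, x_f), "foot Y")
    z_f = np.cross(x_f, y_f)
    foot = _frames_from_axes(x_f, y_f, z_f, ajc, ok_f)
    return {"pelvis": pelvis, "femur": femur, "shank": shank, "foot": foot}
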