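"""End-to-end gait analysis: calibration, angle computation, study analysis.

The cluster (ISB 6DOF) route follows the calibrated anatomical systems
technique: pointer pivot calibration -> landmark registration in each
cluster's technical frame during the static trial -> per-frame cluster pose
estimation in dynamic trials -> virtual-marker reconstruction -> ISB
anatomical frames -> Cardan joint angles -> gait-cycle extraction and
101-point normalisation.  The Helen Hayes route builds frames directly from
skin and wand markers.  Both share the event, filtering and normalisation
machinery so their outputs are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .anatomy import (HipJointCentre, LandmarkSet, build_hh_frames,
                      build_isb_frames, davis_hip_joint_centre)
from .cycles import detect_foot_strikes, filter_marker_set, normalize_cycle
from .io_mocap import MarkerSetConfig, MarkerTrajectorySet, read_angle_curves, \
    read_trial
from .kinematics import AngleTimeSeries, GaitCycleAngles, compute_joint_angles
from .rigid_body import (AnatomicalCalibration, CalibrationError, PointerModel,
                         Pose, PoseSeries, fit_pose_series, pivot_calibrate,
                         register_landmark)

__all__ = [
    "IsbCalibration",
    "calibrate",
    "segment_poses",
    "compute_angles_isb",
    "compute_angles_hh",
    "extract_cycles",
    "analyze_study",
]

DEFAULT_POINTER_LABELS = ("PTR1", "PTR2", "PTR3")


@dataclass
class IsbCalibration:
    """Everything a dynamic ISB 6DOF trial needs: pointer model, cluster
    reference geometries, landmark vectors, HJC and the neutral foot
    attachment."""

    pointer: PointerModel
    anatomical: AnatomicalCalibration
    hjc: HipJointCentre
    neutral_shank_pose: Pose
    config: MarkerSetConfig

    def to_yaml(self, path) -> None:
        payload = {
            "pointer": {
                "labels": list(self.pointer.marker_labels),
                "tip_offset_mm": self.pointer.tip_offset.tolist(),
                "residual_rms_mm": float(self.pointer.residual_rms),
            },
            "hjc_pelvis_mm": self.hjc.local.tolist(),
            "landmarks": {seg: {k: v.tolist() for k, v in d.items()}
                          for seg, d in self.anatomical.landmarks.items()},
            "registration_scatter_mm": {k: float(v) for k, v
                                        in self.anatomical.residuals.items()},
            "neutral_shank_pose": {
                "rotation": self.neutral_shank_pose.rotation.tolist(),
                "translation": self.neutral_shank_pose.translation.tolist(),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _cluster_reference(static: MarkerTrajectorySet, labels: list[str],
                       segment: str) -> np.ndarray:
    """Static-trial mean marker positions: the cluster technical frame.

    With this reference the cluster pose during the static trial is the
    identity, so landmark vectors registered there are directly the technical-
    frame coordinates.
    """
    try:
        pos, valid = static.stack(labels)
    except KeyError as exc:
        raise CalibrationError(f"cluster {segment!r}: {exc}") from exc
    ok = valid.all(axis=1)
    if not ok.any():
        raise CalibrationError(
            f"cluster {segment!r} never fully visible in the static trial")
    return pos[ok].mean(axis=0)


def calibrate(static: MarkerTrajectorySet, pivot: MarkerTrajectorySet,
              config: MarkerSetConfig,
              schedule: dict[str, tuple[int, int]],
              pointer_labels: tuple[str, ...] = DEFAULT_POINTER_LABELS,
              side: str = "right") -> IsbCalibration:
    """Full anatomical calibration from a static trial and a pivot trial.

    ``schedule`` maps each landmark name to the [start, stop) static-trial
    window during which the pointer tip rested on it.  Registration averages
    over the whole window and stores the per-landmark scatter as a residual.
    """
    ppos, pvalid = pivot.stack(list(pointer_labels))
    first = np.flatnonzero(pvalid.all(axis=1))
    if len(first) == 0:
        raise CalibrationError("pointer never fully visible in pivot trial")
    ptr_reference = ppos[first[0]]
    pivot_poses = fit_pose_series(ptr_reference, ppos, pvalid)
    pointer = pivot_calibrate(pivot_poses, pointer_labels, ptr_reference)

    landmark_owner = {name: seg for seg, names in config.landmarks.items()
                      for name in names}
    references = {seg: _cluster_reference(static, labels, seg)
                  for seg, labels in config.clusters.items()}

    spos, svalid = static.stack(list(pointer_labels))
    static_ptr_poses = fit_pose_series(ptr_reference, spos, svalid)

    landmarks: dict[str, dict[str, np.ndarray]] = {s: {} for s in config.clusters}
    residuals: dict[str, float] = {}
    for name, (f0, f1) in schedule.items():
        seg = landmark_owner.get(name)
        if seg is None:
            continue
        cpos, cvalid = static.stack(config.clusters[seg])
        cluster_poses = fit_pose_series(references[seg], cpos[f0:f1],
                                        cvalid[f0:f1])
        ptr_win = PoseSeries(static_ptr_poses.rotations[f0:f1],
                             static_ptr_poses.translations[f0:f1],
                             static_ptr_poses.valid[f0:f1])
        local, scatter = register_landmark(pointer, ptr_win, cluster_poses)
        landmarks[seg][name] = local
        residuals[name] = scatter
    anatomical = AnatomicalCalibration(landmarks, references, residuals)

    a = config.anthropometrics
    hjc = davis_hip_joint_centre(a["leg_length_mm"], a["inter_asis_mm"],
                                 marker_radius=a["marker_radius_mm"], side=side)

    # neutral foot attachment: shank anatomical frame at the static trial
    static_landmarks = LandmarkSet(
        {name: np.broadcast_to(vec, (1, 3)).copy()
         for seg, d in landmarks.items() for name, vec in d.items()},
        {name: np.array([True])
         for seg, d in landmarks.items() for name in d})
    neutral = build_isb_frames(static_landmarks, hjc,
                               foot_technical=PoseSeries.identity(1),
                               neutral_shank_pose=Pose.identity())
    return IsbCalibration(pointer, anatomical, hjc,
                          neutral["shank"].pose(0), config)


def segment_poses(trial: MarkerTrajectorySet,
                  calibration: IsbCalibration) -> dict[str, PoseSeries]:
    """Per-frame technical (cluster) poses of every segment."""
    poses = {}
    for seg, labels in calibration.config.clusters.items():
        pos, valid = trial.stack(labels)
        poses[seg] = fit_pose_series(
            calibration.anatomical.reference_geometry[seg], pos, valid)
    return poses


def _virtual_landmarks(cluster_poses: dict[str, PoseSeries],
                       calibration: IsbCalibration) -> LandmarkSet:
    positions: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for seg, named in calibration.anatomical.landmarks.items():
        for name, vec in named.items():
            positions[name], valid[name] = cluster_poses[seg].apply(vec)
    return LandmarkSet(positions, valid)


def compute_angles_isb(trial: MarkerTrajectorySet,
                       calibration: IsbCalibration,
                       cutoff: float | None = None,
                       ) -> tuple[AngleTimeSeries, LandmarkSet]:
    """Joint angles of one dynamic trial through the cluster/CAST route.

    ``cutoff`` (Hz) applies the zero-lag Butterworth to the marker
    trajectories before pose fitting; None skips filtering.
    """
    if cutoff is not None:
        trial = filter_marker_set(trial, cutoff=cutoff)
    clusters = segment_poses(trial, calibration)
    landmarks = _virtual_landmarks(clusters, calibration)
    frames = build_isb_frames(landmarks, calibration.hjc,
                              foot_technical=clusters["foot"],
                              neutral_shank_pose=calibration.neutral_shank_pose)
    return compute_joint_angles(frames, rate=trial.rate), landmarks


def compute_angles_hh(trial: MarkerTrajectorySet,
                      anthropometrics: dict[str, float],
                      cutoff: float | None = None,
                      ) -> tuple[AngleTimeSeries, LandmarkSet]:
    """Joint angles of one dynamic trial through the Helen Hayes route."""
    if cutoff is not None:
        trial = filter_marker_set(trial, cutoff=cutoff)
    names = ("R_ASIS", "L_ASIS", "SACR", "R_THIGH_WAND", "R_KNEE",
             "R_SHANK_WAND", "R_ANKLE", "R_HEEL", "R_TOE")
    positions, valid = {}, {}
    for n in names:
        try:
            positions[n], valid[n] = trial.get(n)
        except KeyError as exc:
            raise CalibrationError(str(exc)) from exc
    landmarks = LandmarkSet(positions, valid)
    hjc = davis_hip_joint_centre(anthropometrics["leg_length_mm"],
                                 anthropometrics["inter_asis_mm"],
                                 marker_radius=anthropometrics["marker_radius_mm"],
                                 side="right")
    frames = build_hh_frames(landmarks, hjc,
                             knee_width=anthropometrics["knee_width_mm"],
                             ankle_width=anthropometrics["ankle_width_mm"],
                             marker_radius=anthropometrics["marker_radius_mm"])
    return compute_joint_angles(frames, rate=trial.rate), landmarks


def extract_cycles(angles: AngleTimeSeries,
                   events: list[int] | None = None,
                   heel: np.ndarray | None = None,
                   pelvis_origin: np.ndarray | None = None,
                   trial_id: str = "") -> list[GaitCycleAngles]:
    """Cut the angle series into foot-strike-to-foot-strike cycles and
    time-normalise each to 101 samples.

    User-supplied ``events`` (manual cycle selection) always override
    detection; otherwise heel and pelvis trajectories are required.
    """
    if events is None:
        if heel is None or pelvis_origin is None:
            raise ValueError("either events or heel+pelvis trajectories needed")
        events = detect_foot_strikes(heel, pelvis_origin, angles.rate)
    events = sorted(int(e) for e in events)
    if len(events) < 2:
        raise ValueError("need at least two foot strikes for one cycle")
    cycles = []
    for k, (s, e) in enumerate(zip(events[:-1], events[1:])):
        if not angles.valid[s:e + 1].all():
            raise ValueError(
                f"cycle {k} [{s}, {e}] contains invalid samples; "
                "gaps must be resolved explicitly before normalisation")
        cycles.append(GaitCycleAngles(normalize_cycle(angles.values, s, e),
                                      angles.labels, trial_id, k, (s, e)))
    return cycles


def analyze_study(study_dir, protocols: tuple[str, ...] = ("ISB6DOF", "HH"),
                  cutoff: float | None = None, use_manifest_events: bool = True,
                  ) -> tuple[dict[str, dict[str, list[GaitCycleAngles]]], dict]:
    """Run the full pipeline over a generated study directory.

    Returns ({protocol: {subject: [cycles...]}}, manifest).  Ground-truth
    event frames from the manifest mirror the original manual cycle
    selection; set ``use_manifest_events=False`` to exercise the detector.
    """
    study_dir = Path(study_dir)
    with open(study_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    rate = float(manifest["rate"])
    config = MarkerSetConfig.from_yaml(study_dir / manifest["markerset"])
    out: dict[str, dict[str, list[GaitCycleAngles]]] = {p: {} for p in protocols}
    for sid, sub in manifest["subjects"].items():
        static = read_trial(study_dir / sub["static"], rate)
        pivot = read_trial(study_dir / sub["pivot"], rate)
        schedule = {k: tuple(v) for k, v in sub["schedule"].items()}
        cfg = MarkerSetConfig(config.model, config.clusters, config.landmarks,
                              dict(sub["anthropometrics"]))
        calibration = calibrate(static, pivot, cfg, schedule)
        for proto in protocols:
            out[proto][sid] = []
        for j, tr in enumerate(sub["trials"]):
            trial = read_trial(study_dir / tr["file"], rate)
            events = list(tr["events"]) if use_manifest_events else None
            for proto in protocols:
                if proto == "ISB6DOF":
                    angles, lmset = compute_angles_isb(trial, calibration,
                                                       cutoff=cutoff)
                    heel = lmset.positions.get("R_CAL")
                    pelvis_o = 0.5 * (lmset.positions["R_ASIS"]
                                      + lmset.positions["L_ASIS"])
                else:
                    angles, lmset = compute_angles_hh(
                        trial, cfg.anthropometrics, cutoff=cutoff)
                    heel = lmset.positions["R_HEEL"]
                    pelvis_o = 0.5 * (lmset.positions["R_ASIS"]
                                      + lmset.positions["L_ASIS"])
                cycles = extract_cycles(angles, events, heel, pelvis_o,
                                        trial_id=f"{sid}_T{j + 1}")
                out[proto][sid].extend(cycles)
    return out, manifest


def load_ground_truth_cycles(study_dir, manifest: dict,
                             ) -> dict[str, list[GaitCycleAngles]]:
    """Normalised ground-truth cycles per subject, from the stored curves."""
    study_dir = Path(study_dir)
    out: dict[str, list[GaitCycleAngles]] = {}
    for sid, sub in manifest["subjects"].items():
        out[sid] = []
        for j, tr in enumerate(sub["trials"]):
            values, _ = read_angle_curves(study_dir / tr["truth"])
            events = list(tr["events"])
            for k, (s, e) in enumerate(zip(events[:-1], events[1:])):
                out[sid].append(GaitCycleAngles(
                    normalize_cycle(values, s, e),
                    trial_id=f"{sid}_T{j + 1}", cycle_index=k, events=(s, e)))
    return out
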