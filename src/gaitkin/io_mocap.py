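"""Marker-trajectory containers and file I/O (C3D, CSV, YAML configuration).

Internal units are millimetres and degrees throughout; C3D unit metadata is
honoured on import.  Gaps are represented explicitly through a per-label,
per-frame validity mask and are never filled implicitly — short gaps may be
repaired only through the explicit :func:`fill_gaps` operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import c3dio
from .kinematics import ROTATION_LABELS

__all__ = [
    "FormatError",
    "MarkerTrajectorySet",
    "MarkerSetConfig",
    "read_c3d",
    "write_c3d",
    "read_csv_trajectories",
    "write_csv_trajectories",
    "read_trial",
    "write_trial",
    "write_angle_curves",
    "read_angle_curves",
    "fill_gaps",
]

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


class FormatError(ValueError):
    """Unreadable or malformed input file."""


@dataclass
class MarkerTrajectorySet:
    """Labelled 3-D marker position time series (mm) with gap mask."""

    labels: list[str]
    positions: np.ndarray    # (T, n, 3) mm; NaN where invalid
    rate: float              # Hz
    valid_mask: np.ndarray   # (T, n) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.valid_mask = np.asarray(self.valid_mask, bool)
        T, n = self.positions.shape[:2]
        if n != len(self.labels):
            raise ValueError("labels/positions column mismatch")
        if self.positions.shape != (T, n, 3):
            raise ValueError("positions must be (T, n, 3)")
        if self.valid_mask.shape != (T, n):
            raise ValueError("valid_mask must be (T, n)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.positions[self.valid_mask])):
            raise ValueError("non-finite coordinates flagged valid")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not present "
                           f"(have {sorted(self.labels)})")

    def get(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions (T,3), valid (T,)) for one marker."""
        i = self.index(label)
        return self.positions[:, i, :], self.valid_mask[:, i]

    def stack(self, labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(positions (T,m,3), valid (T,m)) for a marker subset, in order."""
        idx = [self.index(lb) for lb in labels]
        return self.positions[:, idx, :], self.valid_mask[:, idx]

    def window(self, start: int, stop: int) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(list(self.labels),
                                   self.positions[start:stop].copy(),
                                   self.rate, self.valid_mask[start:stop].copy())


# ---------------------------------------------------------------------------
# marker-set configuration

DEFAULT_ANTHROPOMETRICS = {
    "leg_length_mm": 890.0,
    "inter_asis_mm": 240.0,
    "marker_radius_mm": 0.0,
    "knee_width_mm": 110.0,
    "ankle_width_mm": 90.0,
}


@dataclass
class MarkerSetConfig:
    """Which markers form each cluster, landmark labels, anthropometrics."""

    model: str                                   # "ISB6DOF" or "HH"
    clusters: dict[str, list[str]] = field(default_factory=dict)
    landmarks: dict[str, list[str]] = field(default_factory=dict)  # segment -> names
    anthropometrics: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANTHROPOMETRICS))

    def __post_init__(self) -> None:
        if self.model not in ("ISB6DOF", "HH"):
            raise ValueError(f"unknown model {self.model!r}")
        for seg, labels in self.clusters.items():
            if len(set(labels)) < 3:
                raise ValueError(
                    f"cluster {seg!r} needs >= 3 distinct technical markers")
        for key, val in self.anthropometrics.items():
            if key != "marker_radius_mm" and val <= 0:
                raise ValueError(f"anthropometric {key} must be positive")
            if val < 0:
                raise ValueError(f"anthropometric {key} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "MarkerSetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(model=raw["model"],
                   clusters={k: list(v) for k, v in raw.get("clusters", {}).items()},
                   landmarks={k: list(v) for k, v in raw.get("landmarks", {}).items()},
                   anthropometrics={**DEFAULT_ANTHROPOMETRICS,
                                    **raw.get("anthropometrics", {})})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"model": self.model, "clusters": self.clusters,
                            "landmarks": self.landmarks,
                            "anthropometrics": self.anthropometrics}, fh,
                           sort_keys=False)


# ---------------------------------------------------------------------------
# C3D

def read_c3d(path) -> MarkerTrajectorySet:
    """Import all POINT trajectories from a C3D file, converted to mm.

    Samples with a negative residual (the C3D gap convention) are flagged
    invalid in ``valid_mask``.
    """
    try:
        data = c3dio.read_c3d_file(path)
    except c3dio.C3DFormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    except OSError as exc:
        raise FormatError(f"{path}: unreadable ({exc})") from exc
    unit = data.units.strip().lower()
    factor = _UNIT_TO_MM.get(unit)
    if factor is None:
        raise FormatError(f"{path}: unknown POINT:UNITS {data.units!r}")
    valid = (data.residuals >= 0) & np.all(np.isfinite(data.points), axis=2)
    pos = data.points * factor
    pos[~valid] = np.nan
    return MarkerTrajectorySet(list(data.labels), pos, data.rate, valid)


def write_c3d(mset: MarkerTrajectorySet, path, units: str = "mm") -> None:
    factor = _UNIT_TO_MM[units]
    pos = np.where(np.isfinite(mset.positions), mset.positions, 0.0) / factor
    residuals = np.where(mset.valid_mask, 0.0, -1.0)
    c3dio.write_c3d_file(path, mset.labels, pos, residuals, mset.rate, units)


# ---------------------------------------------------------------------------
# CSV dialect: header "frame,<label>_x,<label>_y,<label>_z,..."; blank = gap

def read_csv_trajectories(path, rate: float) -> MarkerTrajectorySet:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.columns[0] != "frame":
        raise FormatError(f"{path}: first column must be 'frame'")
    coord_cols = list(df.columns[1:])
    if len(coord_cols) == 0 or len(coord_cols) % 3:
        raise FormatError(
            f"{path}: coordinate columns ({len(coord_cols)}) not a multiple of 3")
    frames = df["frame"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        raise FormatError(f"{path}: frame column must be strictly increasing")
    labels = []
    for i in range(0, len(coord_cols), 3):
        trio = coord_cols[i:i + 3]
        stems = [c.rsplit("_", 1) for c in trio]
        if [s[1] for s in stems] != ["x", "y", "z"] or len({s[0] for s in stems}) != 1:
            raise FormatError(f"{path}: columns {trio} are not <label>_x/_y/_z")
        labels.append(stems[0][0])
    pos = df[coord_cols].to_numpy(float).reshape(len(df), len(labels), 3)
    valid = np.all(np.isfinite(pos), axis=2)
    pos[~valid] = np.nan
    return MarkerTrajectorySet(labels, pos, rate, valid)


def write_csv_trajectories(mset: MarkerTrajectorySet, path) -> None:
    cols = {"frame": np.arange(mset.n_frames)}
    for j, label in enumerate(mset.labels):
        xyz = np.where(mset.valid_mask[:, j, None], mset.positions[:, j, :], np.nan)
        for k, ax in enumerate("xyz"):
            cols[f"{label}_{ax}"] = xyz[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9f")


def read_trial(path, rate: float | None = None) -> MarkerTrajectorySet:
    """Read a trial by extension (.c3d or .csv)."""
    p = Path(path)
    if p.suffix.lower() == ".c3d":
        return read_c3d(p)
    if rate is None:
        raise ValueError("rate is required for CSV trials")
    return read_csv_trajectories(p, rate)


def write_trial(mset: MarkerTrajectorySet, path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".c3d":
        write_c3d(mset, p)
    else:
        write_csv_trajectories(mset, p)


# ---------------------------------------------------------------------------
# angle curves

def write_angle_curves(values: np.ndarray, path,
                       labels: tuple[str, ...] = ROTATION_LABELS) -> None:
    """Write rotation curves as CSV: one row per sample, one column per rotation.

    For gait-cycle output ``values`` is (101, 12) with the 12 rotations in the
    conventional report order held by ``ROTATION_LABELS``.
    """
    arr = np.asarray(values, float)
    if arr.ndim != 2 or arr.shape[1] != len(labels):
        raise ValueError(
            f"expected (n, {len(labels)}) curves for labels {labels}, "
            f"got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle curves contain non-finite samples")
    try:
        pd.DataFrame(arr, columns=list(labels)).to_csv(
            path, index_label="sample", float_format="%.12f")
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_angle_curves(path) -> tuple[np.ndarray, tuple[str, ...]]:
    try:
        df = pd.read_csv(path, index_col="sample")
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return df.to_numpy(float), tuple(df.columns)


# ---------------------------------------------------------------------------
# gap repair (explicit only)

def fill_gaps(mset: MarkerTrajectorySet, max_gap: int = 10) -> MarkerTrajectorySet:
    """Fill interior gaps no longer than ``max_gap`` frames by cubic interpolation.

    Longer gaps and gaps touching either end of the trial are left invalid.
    """
    from scipy.interpolate import CubicSpline

    pos = mset.positions.copy()
    valid = mset.valid_mask.copy()
    for j in range(len(mset.labels)):
        v = valid[:, j]
        if v.all() or v.sum() < 4:
            continue
        bad = ~v
        starts = np.flatnonzero(bad & ~np.r_[False, bad[:-1]])
        spline = CubicSpline(np.flatnonzero(v), pos[v, j, :], axis=0)
        for s in starts:
            e = s
            while e < len(v) and bad[e]:
                e += 1
            if s == 0 or e == len(v) or (e - s) > max_gap:
                continue
            idx = np.arange(s, e)
            pos[idx, j, :] = spline(idx)
            valid[idx, j] = True
    return MarkerTrajectorySet(list(mset.labels), pos, mset.rate, valid)
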