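"""Repeatability and protocol-comparison statistics for gait-cycle angles.

All statistics operate on 101-sample normalised rotation curves, in degrees:

AIT  (average intertrial variability)  — per subject, the sample SD across that
     subject's trials at each cycle sample; averaged over the 101 samples,
     then over subjects.
AIP  (averaged intraprotocol variability) — the sample SD across the subjects'
     mean curves at each sample, averaged over the cycle: subject-to-subject
     variability.
MAV  (mean absolute variability) — per subject, the mean over the cycle of the
     absolute difference between two protocols' curves; averaged over subjects.
ROM  (range of motion) — max minus min of a curve over the cycle.

Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import ROTATION_LABELS, GaitCycleAngles

__all__ = [
    "ensemble_mean_sd",
    "intertrial_sd_curve",
    "average_intertrial_variability",
    "averaged_intraprotocol_variability",
    "mean_absolute_variability",
    "range_of_motion",
    "VariabilityReport",
    "build_report",
]


def _stack(cycles: list[GaitCycleAngles] | np.ndarray) -> np.ndarray:
    """(n, 101, 12) array from a list of cycles (validating the rotation set)."""
    if isinstance(cycles, np.ndarray):
        arr = np.asarray(cycles, float)
        if arr.ndim == 2:
            arr = arr[None]
        return arr
    if not cycles:
        raise ValueError("no cycles supplied")
    labels = cycles[0].labels
    for c in cycles:
        if c.labels != labels:
            raise ValueError("cycles do not share the same rotation set")
    return np.stack([c.values for c in cycles])


def ensemble_mean_sd(cycles: list[GaitCycleAngles] | np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mean and sample SD (n-1) across cycles: (101, 12) each."""
    arr = _stack(cycles)
    if arr.shape[0] < 2:
        raise ValueError("at least 2 cycles are required for an ensemble SD")
    return arr.mean(axis=0), arr.std(axis=0, ddof=1)


def intertrial_sd_curve(trials: list[GaitCycleAngles] | np.ndarray,
                        subject: str | None = None) -> np.ndarray:
    """Per-sample SD across one subject's trials, (101, 12).

    When the cycles carry trial ids of the form ``<subject>_...`` a mixed-
    subject input is rejected.
    """
    if (not isinstance(trials, np.ndarray)) and subject is not None:
        owners = {c.trial_id.split("_")[0] for c in trials if c.trial_id}
        if len(owners) > 1:
            raise ValueError(f"trials belong to several subjects: {sorted(owners)}")
    arr = _stack(trials)
    if arr.shape[0] < 2:
        raise ValueError("at least 2 trials are required")
    return arr.std(axis=0, ddof=1)


def average_intertrial_variability(per_subject_sd_curves: list[np.ndarray],
                                   ) -> np.ndarray:
    """AIT per rotation: SD curves averaged over samples, then subjects. (12,)"""
    if len(per_subject_sd_curves) == 0:
        raise ValueError("need at least one subject SD curve")
    per_subject = np.stack([np.asarray(c, float).mean(axis=0)
                            for c in per_subject_sd_curves])
    return per_subject.mean(axis=0)


def averaged_intraprotocol_variability(subject_mean_cycles: list[np.ndarray],
                                       ) -> np.ndarray:
    """AIP per rotation: across-subject SD of mean curves, cycle-averaged. (12,)"""
    if len(subject_mean_cycles) < 2:
        raise ValueError("AIP needs mean cycles from at least 2 subjects")
    arr = np.stack([np.asarray(c, float) for c in subject_mean_cycles])
    return arr.std(axis=0, ddof=1).mean(axis=0)


def mean_absolute_variability(cycles_a: dict[str, np.ndarray],
                              cycles_b: dict[str, np.ndarray]) -> np.ndarray:
    """MAV per rotation between two protocols, paired by subject. (12,)

    Inputs map subject id -> that subject's mean cycle (101, 12) under each
    protocol; every subject must appear in both.
    """
    if set(cycles_a) != set(cycles_b):
        missing = set(cycles_a) ^ set(cycles_b)
        raise ValueError(f"subjects not paired across protocols: {sorted(missing)}")
    if not cycles_a:
        raise ValueError("no paired subjects")
    per_subject = [np.abs(np.asarray(cycles_a[s], float)
                          - np.asarray(cycles_b[s], float)).mean(axis=0)
                   for s in sorted(cycles_a)]
    return np.stack(per_subject).mean(axis=0)


def range_of_motion(curve: np.ndarray) -> np.ndarray:
    """Max minus min over the cycle; works per column for (101, k) input."""
    c = np.asarray(curve, float)
    if not np.all(np.isfinite(c)):
        raise ValueError("ROM requires a finite curve")
    return c.max(axis=0) - c.min(axis=0)


@dataclass
class VariabilityReport:
    """Per-rotation repeatability summary across a whole study."""

    labels: tuple[str, ...]
    ait: dict[str, np.ndarray]            # protocol -> (12,)
    aip: dict[str, np.ndarray]            # protocol -> (12,)
    mav: np.ndarray | None                # (12,) between the two protocols
    intertrial_curves: dict[str, np.ndarray]   # protocol -> (101, 12) subject-avg
    rom: dict[str, np.ndarray]            # protocol -> (12,) mean per-cycle ROM
    n_subjects: int = 0
    n_trials: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for proto in self.ait:
            cols[f"AIT_{proto}"] = self.ait[proto]
        for proto in self.aip:
            cols[f"AIP_{proto}"] = self.aip[proto]
        if self.mav is not None:
            cols["MAV"] = self.mav
        for proto in self.rom:
            cols[f"ROM_{proto}"] = self.rom[proto]
        return pd.DataFrame(cols, index=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="rotation",
                               float_format="%.6f")


def build_report(study: dict[str, dict[str, list[GaitCycleAngles]]],
                 ) -> VariabilityReport:
    """Assemble AIT/AIP/MAV/ROM from {protocol: {subject: [cycles...]}}."""
    labels = ROTATION_LABELS
    ait: dict[str, np.ndarray] = {}
    aip: dict[str, np.ndarray] = {}
    it_curves: dict[str, np.ndarray] = {}
    rom: dict[str, np.ndarray] = {}
    subject_means: dict[str, dict[str, np.ndarray]] = {}
    n_sub = n_tri = 0
    for proto, by_subject in study.items():
        sd_curves, means, roms = [], {}, []
        for subject, cycles in sorted(by_subject.items()):
            sd_curves.append(intertrial_sd_curve(cycles, subject=subject))
            means[subject] = _stack(cycles).mean(axis=0)
            roms.extend(range_of_motion(c.values) for c in cycles)
        ait[proto] = average_intertrial_variability(sd_curves)
        aip[proto] = averaged_intraprotocol_variability(list(means.values()))
        it_curves[proto] = np.stack(sd_curves).mean(axis=0)
        rom[proto] = np.stack(roms).mean(axis=0)
        subject_means[proto] = means
        n_sub = len(by_subject)
        n_tri = sum(len(c) for c in by_subject.values())
    mav = None
    protos = sorted(study)
    if len(protos) == 2:
        mav = mean_absolute_variability(subject_means[protos[0]],
                                        subject_means[protos[1]])
    return VariabilityReport(labels, ait, aip, mav, it_curves, rom,
                             n_subjects=n_sub, n_trials=n_tri)
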