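"""Trajectory filtering, gait-event detection and time normalisation.

The low-pass stage follows standard gait-lab practice: a 4th-order zero-lag
Butterworth at 6 Hz realised as a forward-backward pass of a 2nd-order filter
whose cutoff is raised by the dual-pass correction factor, so the *effective*
filter is 4th order with its -3 dB point at the requested cutoff.  A gait
cycle runs from one foot strike to the next ipsilateral foot strike and is
resampled to 101 points (0..100 % of the cycle).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "butterworth_lowpass",
    "filter_marker_set",
    "detect_foot_strikes",
    "normalize_cycle",
    "EventDetectionError",
]


class EventDetectionError(RuntimeError):
    pass


def butterworth_lowpass(series: np.ndarray, rate: float, cutoff: float = 6.0,
                        order: int = 4, mode: str = "effective") -> np.ndarray:
    """Zero-phase Butterworth low pass along axis 0.

    mode="effective" (default): dual-pass filter of order ``order // 2`` with
    the cutoff-correction factor ``(2**(1/2) - 1)**(-1/(2*(order//2)))`` so the
    combined response is of the requested order with unit DC gain and -3 dB at
    ``cutoff``.  mode="per_pass" designs each pass at the requested order and
    cutoff (the combined -3 dB point then falls below ``cutoff``).
    """
    x = np.asarray(series, float)
    if rate <= 2 * cutoff:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate / 2} Hz)")
    if mode not in ("effective", "per_pass"):
        raise ValueError("mode must be 'effective' or 'per_pass'")
    if mode == "effective":
        if order % 2:
            raise ValueError("effective mode requires an even order")
        n_pass = order // 2
        correction = (2 ** 0.5 - 1) ** (-1.0 / (2 * n_pass))
        wc = cutoff * correction
    else:
        n_pass = order
        wc = cutoff
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot filter series containing gaps (fill gaps first)")
    if x.shape[0] < 3 * order:
        raise ValueError(
            f"series of {x.shape[0]} samples is too short for order {order}")
    padlen = min(x.shape[0] - 1, max(3 * n_pass, int(round(3 * rate / cutoff))))
    b, a = signal.butter(n_pass, wc / (rate / 2))
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def filter_marker_set(mset, cutoff: float = 6.0, order: int = 4,
                      mode: str = "effective"):
    """Filter every fully valid marker trajectory of a MarkerTrajectorySet.

    Markers with gaps are passed through untouched rather than filtered across
    invalid samples (gaps must be resolved explicitly first).
    """
    from .io_mocap import MarkerTrajectorySet

    pos = mset.positions.copy()
    for j in range(len(mset.labels)):
        if mset.valid_mask[:, j].all():
            pos[:, j, :] = butterworth_lowpass(pos[:, j, :], mset.rate,
                                               cutoff, order, mode)
    return MarkerTrajectorySet(list(mset.labels), pos, mset.rate,
                               mset.valid_mask.copy())


def detect_foot_strikes(heel: np.ndarray, pelvis_origin: np.ndarray,
                        rate: float, progression_axis: int | None = None,
                        min_cycle_s: float = 0.6) -> list[int]:
    """Foot-strike frames by the coordinate-based method.

    Foot strike is taken at local maxima of the heel position along the
    direction of progression, measured relative to the pelvis origin.  The
    progression axis defaults to the lab axis with the largest pelvis
    displacement.  Returns sorted event frames; raises when no periodic
    forward motion is found.  Manually selected events always take precedence
    over this detector in the pipeline.
    """
    heel = np.asarray(heel, float)
    pelvis_origin = np.asarray(pelvis_origin, float)
    if heel.shape != pelvis_origin.shape or heel.ndim != 2:
        raise ValueError("heel and pelvis trajectories must both be (T, 3)")
    disp = pelvis_origin[-1] - pelvis_origin[0]
    if progression_axis is None:
        progression_axis = int(np.argmax(np.abs(disp)))
    direction = np.sign(disp[progression_axis])
    if direction == 0 or np.abs(disp[progression_axis]) < 100.0:
        raise EventDetectionError(
            "no forward progression found (stationary markers?)")
    rel = direction * (heel[:, progression_axis] - pelvis_origin[:, progression_axis])
    distance = max(int(round(min_cycle_s * rate)), 1)
    peaks, _ = signal.find_peaks(rel, distance=distance,
                                 prominence=0.05 * np.ptp(rel))
    if len(peaks) < 2:
        raise EventDetectionError(
            f"found {len(peaks)} foot strikes; need at least one full stride")
    return sorted(int(p) for p in peaks)


def normalize_cycle(curve: np.ndarray, start: int, end: int) -> np.ndarray:
    """Resample one gait cycle onto 101 equally spaced points of [start, end].

    Linear interpolation between capture frames; the endpoints are preserved
    exactly.  Works on (T,) or (T, k) curves; invalid (non-finite) samples
    inside the window are an error — gaps must be resolved upstream.
    """
    c = np.asarray(curve, float)
    if not (0 <= start < end < c.shape[0]):
        raise ValueError(f"invalid cycle window [{start}, {end}] "
                         f"for {c.shape[0]} frames")
    seg = c[start:end + 1]
    if not np.all(np.isfinite(seg)):
        raise ValueError("cycle window contains invalid samples")
    t = np.linspace(start, end, 101)
    frames = np.arange(start, end + 1)
    if seg.ndim == 1:
        return np.interp(t, frames, seg)
    out = np.empty((101,) + seg.shape[1:])
    for j in range(seg.shape[1]):
        out[:, j] = np.interp(t, frames, seg[:, j])
    return out
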