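"""Mean ± SD band figures for normalised gait curves."""

from __future__ import annotations

import numpy as np

from .kinematics import ROTATION_LABELS, GaitCycleAngles
from .variability import ensemble_mean_sd

_PRETTY = {
    "pelvis_tilt": "Pelvis tilt", "pelvis_obliquity": "Pelvis obliquity",
    "pelvis_rotation": "Pelvis rotation", "hip_flexion": "Hip flex/ext",
    "hip_adduction": "Hip abd/add", "hip_rotation": "Hip int/ext",
    "knee_flexion": "Knee flex/ext", "knee_varus": "Knee var/valg",
    "knee_rotation": "Knee int/ext", "ankle_dorsiflexion": "Ankle dor/pla",
    "ankle_inversion": "Ankle inv/ev", "ankle_adduction": "Ankle abd/add",
}


def plot_mean_sd_bands(cycles_by_protocol: dict[str, list[GaitCycleAngles]],
                       path, title: str = "") -> None:
    """3x4 grid of rotation curves with +/- 1 SD bands, one line per protocol."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(101)
    fig, axes = plt.subplots(4, 3, figsize=(11, 12), sharex=True)
    styles = [dict(color="k", ls="-"), dict(color="0.5", ls="--")]
    for p, (proto, cycles) in enumerate(sorted(cycles_by_protocol.items())):
        mean, sd = ensemble_mean_sd(cycles)
        for j, label in enumerate(ROTATION_LABELS):
            ax = axes.flat[j]
            ax.plot(x, mean[:, j], label=proto, **styles[p % 2])
            ax.fill_between(x, mean[:, j] - sd[:, j], mean[:, j] + sd[:, j],
                            alpha=0.15, color=styles[p % 2]["color"])
            ax.set_title(_PRETTY[label], fontsize=9)
    for ax in axes[-1]:
        ax.set_xlabel("% gait cycle")
    for ax in axes[:, 0]:
        ax.set_ylabel("deg")
    axes.flat[0].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_intertrial_sd(curves_by_protocol: dict[str, np.ndarray], path) -> None:
    """Intertrial-variability patterns across the cycle, per rotation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(101)
    fig, axes = plt.subplots(4, 3, figsize=(11, 12), sharex=True)
    styles = [dict(color="k", ls="-"), dict(color="0.5", ls="--")]
    for p, (proto, sd) in enumerate(sorted(curves_by_protocol.items())):
        for j, label in enumerate(ROTATION_LABELS):
            ax = axes.flat[j]
            ax.plot(x, sd[:, j], label=proto, **styles[p % 2])
            ax.set_title(_PRETTY[label], fontsize=9)
    for ax in axes[-1]:
        ax.set_xlabel("% gait cycle")
    for ax in axes[:, 0]:
        ax.set_ylabel("SD (deg)")
    axes.flat[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
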