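"""Static plotting convenience: a lateral (sagittal) view of a posture."""

from __future__ import annotations

import numpy as np

from .model import SpinePosture


def plot_lateral(posture: SpinePosture, ax=None, show_spline: bool = True):
    """Lateral-view (x anterior vs z vertical) plot of joints, spinous tips
    and skin surface.  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 7))
    ax.plot(posture.joints[:, 0], posture.joints[:, 2], "o-", label="joint chain", ms=4)
    ax.plot(
        posture.spinous_tips[:, 0], posture.spinous_tips[:, 2],
        "s", ms=3, color="tab:orange", label="spinous tips",
    )
    ax.plot(
        posture.skin_points[:, 0], posture.skin_points[:, 2],
        "o", ms=3, mfc="white", mec="gray", label="skin points",
    )
    if show_spline:
        lo, hi = posture.skin_spline.domain
        u = np.linspace(lo, hi, 200)
        curve = posture.skin_spline.position(u)
        ax.plot(curve[:, 0], curve[:, 2], "-", color="gray", lw=1, label="skin spline")
    ax.set_xlabel("anterior x (cm)")
    ax.set_ylabel("vertical z (cm)")
    ax.set_aspect("equal")
    ax.legend(fontsize=7)
    return ax
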