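"""Simple target/response scatter plots, one panel per condition."""

from __future__ import annotations

import numpy as np

from .task import Condition


def plot_condition_scatter(targets, responses=None, condition: Condition | None = None, ax=None):
    """Scatter targets (and optionally responses) over the beacon layout.

    ``targets``/``responses`` are (n, 2) arrays in meters.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    t = np.asarray(targets, dtype=float)
    ax.scatter(t[:, 0], t[:, 1], s=8, alpha=0.25, label="targets", color="tab:blue")
    if responses is not None:
        r = np.asarray(responses, dtype=float)
        ax.scatter(r[:, 0], r[:, 1], s=8, alpha=0.25, label="responses", color="tab:orange")
    if condition is not None:
        b = condition.layout.beacon_array
        ax.scatter(b[:, 0], b[:, 1], marker="s", s=60, color="0.3", label="beacons")
        circle = plt.Circle((0, 0), condition.layout.circle_radius, fill=False, ls=":")
        ax.add_patch(circle)
        if condition.prior.kind == "ring":
            cx, cy = condition.prior.center
            ax.add_patch(
                plt.Circle((cx, cy), condition.prior.ring_radius_mean, fill=False,
                           color="tab:green", ls="--", label="prior mode")
            )
        else:
            cx, cy = condition.prior.center
            ax.scatter([cx], [cy], marker="D", s=60, color="tab:green", label="prior mode")
        ax.set_title(condition.name)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.legend(loc="upper right", fontsize=8)
    return ax
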