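"""Quick-look plots for trajectories, scans and phase portraits.

Thin matplotlib/seaborn wrappers; each function accepts an existing ``ax``
and returns it, so figures can be composed by the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiments import ScanGrid
from .model_core import Trajectory

__all__ = ["plot_trajectory", "plot_scan_heatmap", "plot_phase_portrait"]


def plot_trajectory(trajectory: Trajectory, ax=None):
    """Time series of demand E(t) and organelle supply x_m(t)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trajectory.time, trajectory.demand, label="demand E(t)",
            color="0.4", lw=1)
    ax.plot(trajectory.time, trajectory.x_m,
            label=f"supply x_m(t), alpha={trajectory.params.alpha}")
    ax.set_xlabel("time (T-units)")
    ax.set_ylabel("amount (demand units)")
    ax.legend()
    return ax


def plot_scan_heatmap(scan: ScanGrid, metric: str = "difference", ax=None,
                      **heatmap_kwargs):
    """Heatmap of a scan metric (difference c_1 - c_0 by default).

    Positive values favour organelle encoding; a diverging palette centred
    at zero marks the favourability boundary.
    """
    import matplotlib.pyplot as plt
    import seaborn as sns

    if ax is None:
        _, ax = plt.subplots()
    values = getattr(scan, metric if metric != "c0" else "cost_organelle")
    frame = pd.DataFrame(np.asarray(values, dtype=float),
                         index=np.round(scan.axis1_values, 4),
                         columns=np.round(scan.axis2_values, 4))
    defaults = {"center": 0.0, "cmap": "RdBu"} if metric == "difference" else {}
    sns.heatmap(frame, ax=ax, **{**defaults, **heatmap_kwargs})
    ax.set_xlabel(scan.axis2_name)
    ax.set_ylabel(scan.axis1_name)
    return ax


def plot_phase_portrait(portrait: pd.DataFrame, ax=None):
    """Demand-versus-supply trace; the diagonal is perfect matching."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(portrait["E"], portrait["x_m"], lw=0.8)
    lim = max(portrait["E"].max(), portrait["x_m"].max()) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", color="0.6", lw=0.8)
    ax.set_xlabel("demand E(t)")
    ax.set_ylabel("supply x_m(t)")
    ax.set_aspect("equal")
    return ax
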