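"""Diagnostic figures for trajectories and tundra-area series.

Thin matplotlib wrappers over the metrics/area outputs; they return the
figure so callers can style or save it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_lag_trajectory", "plot_tundra_series"]


def plot_lag_trajectory(trajectories: dict, ax=None):
    """Simulated vs analogue treeline fraction, one line per run.

    ``trajectories`` maps a label to a list of TrajectoryPoint.  The
    diagonal is climate–treeline equilibrium: below it the treeline lags
    the climate, above it the treeline overshoots.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], color="0.6", lw=1, ls="--", label="equilibrium")
    for label, traj in trajectories.items():
        x = [pt.analogue_fraction for pt in traj]
        y = [pt.simulated_fraction for pt in traj]
        ax.plot(x, y, marker=".", lw=1, label=str(label))
    ax.set_xlabel("climate-analogue position (fraction of corridor)")
    ax.set_ylabel("simulated treeline position (fraction of corridor)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, loc="lower right")
    return ax.figure


def plot_tundra_series(tundra: pd.DataFrame, ax=None):
    """Remaining tundra fraction over time, one line per variant.

    Accepts the tidy table from the experiment module (columns variant,
    repeat, year, fraction_of_initial); repeats are averaged.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    mean = tundra.groupby(["variant", "year"])["fraction_of_initial"].mean().reset_index()
    for variant, grp in mean.groupby("variant"):
        ax.plot(grp["year"], grp["fraction_of_initial"], lw=1.2, label=str(variant))
    ax.set_xlabel("year CE")
    ax.set_ylabel("remaining tundra (fraction of initial)")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    return ax.figure
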