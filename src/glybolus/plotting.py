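"""Basic diagnostic plots: CGM trace with therapy events, and the CVGA grid."""

from __future__ import annotations

import numpy as np

from .metrics import cvga_points
from .simulate import SimulationLog


def plot_trace(log: SimulationLog, ax=None):
    """CGM trace with the glycemic target band, meals and boluses marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    ax.axhspan(70, 180, color="tab:green", alpha=0.12, lw=0)
    ax.plot(log.cgm.times / 60.0, log.cgm.values, lw=0.8, color="tab:blue",
            label="CGM")
    for m in log.meals:
        ax.axvline(m.start_time / 60.0, color="tab:orange", alpha=0.3, lw=0.8)
    for b in log.boluses:
        ax.plot(b.time / 60.0, 45, marker="v", color="tab:red", ms=4)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("glucose (mg/dL)")
    ax.set_ylim(40, 400)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_cvga(logs_by_method: dict, ax=None):
    """CVGA scatter (one dot per day) for one or more methods.

    The x axis runs from a daily minimum of 110 down to 50 mg/dL, the y axis
    from a daily maximum of 110 up to 400; the nine zones are drawn as grid
    cells with A at the lower left.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for x in (70, 90):
        ax.axvline(x, color="k", lw=0.6)
    for y in (180, 300):
        ax.axhline(y, color="k", lw=0.6)
    labels = {(100, 145): "A", (80, 145): "Lower B", (100, 240): "Upper B",
              (80, 240): "B", (60, 145): "Lower C", (100, 350): "Upper C",
              (60, 240): "Lower D", (80, 350): "Upper D", (60, 350): "E"}
    for (x, y), z in labels.items():
        ax.text(x, y, z, ha="center", va="center", fontsize=9, alpha=0.5)
    for method, log in logs_by_method.items():
        pts = cvga_points(log.cgm)
        mins = np.clip([p["day_min_bg"] for p in pts], 50, 110)
        maxs = np.clip([p["day_max_bg"] for p in pts], 110, 400)
        ax.plot(mins, maxs, "o", ms=4, alpha=0.7, label=method)
    ax.set_xlim(110, 50)  # reversed: better control to the left
    ax.set_ylim(110, 400)
    ax.set_xlabel("daily minimum BG (mg/dL)")
    ax.set_ylabel("daily maximum BG (mg/dL)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_learning_curve(curve, ax=None):
    """Critic loss and reward per update from a training result."""
    import matplotlib.pyplot as plt
    import pandas as pd

    df = pd.DataFrame(curve)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(df["update"], df["critic_loss"], lw=0.7, label="critic loss")
    ax2 = ax.twinx()
    ax2.plot(df["update"], df["reward"].rolling(25, min_periods=1).mean(),
             lw=0.9, color="tab:orange", label="reward (rolling)")
    ax.set_xlabel("update")
    ax.set_ylabel("critic loss")
    ax2.set_ylabel("meal reward")
    return ax
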