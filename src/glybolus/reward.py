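"""Postprandial reward: a step function of each CGM reading, averaged over
the postprandial window.

The per-reading score rewards normoglycemia and penalizes excursions, with
hypoglycemia penalized harder than hyperglycemia of comparable depth:

    +0.5  for 70 <= G <= 180
    -0.8  for 180 < G <= 300
    -1.0  for 300 < G <= 350
    -1.5  for 30 <= G < 70
    -2.0  otherwise

The meal reward is the arithmetic mean of the per-reading score over the CGM
samples strictly after the meal start up to and including
``min(meal + 5 h, next meal)``. Averaging over samples (rather than dividing
by elapsed clock time) keeps the reward independent of the sampling unit.
"""

from __future__ import annotations

import numpy as np

from .patient import CGMTrace

__all__ = ["per_reading_reward", "meal_reward", "POSTPRANDIAL_WINDOW_MIN"]

#: Cap on the postprandial evaluation window, min (5 h).
POSTPRANDIAL_WINDOW_MIN = 300.0

REWARD_MAX = 0.5
REWARD_MIN = -2.0


def per_reading_reward(g: float) -> float:
    """Step reward for a single CGM reading ``g`` (mg/dL)."""
    if not g > 0:
        raise ValueError("glucose reading must be positive")
    if 70.0 <= g <= 180.0:
        return 0.5
    if 180.0 < g <= 300.0:
        return -0.8
    if 300.0 < g <= 350.0:
        return -1.0
    if 30.0 <= g < 70.0:
        return -1.5
    return -2.0


def _reward_array(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, -2.0)
    out[(30.0 <= v) & (v < 70.0)] = -1.5
    out[(300.0 < v) & (v <= 350.0)] = -1.0
    out[(180.0 < v) & (v <= 300.0)] = -0.8
    out[(70.0 <= v) & (v <= 180.0)] = 0.5
    return out


def meal_reward(trace: CGMTrace, meal_time: float,
                next_meal_time: float | None = None) -> float:
    """Mean per-reading reward over the postprandial window of one meal.

    The window runs over CGM samples with ``meal_time < t <= ts*`` where
    ``ts* = min(meal_time + 300, next_meal_time)``. Raises if the trace has
    no samples in the window.
    """
    end = meal_time + POSTPRANDIAL_WINDOW_MIN
    if next_meal_time is not None:
        end = min(end, next_meal_time)
    window = trace.window(meal_time, end)
    if len(window) == 0:
        raise ValueError(
            f"no CGM samples in postprandial window ({meal_time}, {end}]")
    return float(np.mean(_reward_array(window.values)))
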