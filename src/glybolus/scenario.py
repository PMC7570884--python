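"""Meal scenario generation: the three-meal daily protocol with realistic
variability (meal-time jitter, meal-size CV, carbohydrate misestimation)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import MealProtocol
from .patient import MINUTES_PER_DAY

__all__ = ["MealEvent", "Scenario", "generate_scenario"]


@dataclass(frozen=True)
class MealEvent:
    """One meal: carbs are delivered at a constant rate over ``duration``.

    ``true_carbs`` is what the gut receives; ``announced_carbs`` is the
    patient's (possibly mis-)estimate, which is all the bolus calculator and
    the agent ever see.
    """

    start_time: float       # min since scenario start
    true_carbs: float       # g
    announced_carbs: float  # g
    duration: float = 15.0  # min

    def __post_init__(self) -> None:
        if not self.true_carbs > 0:
            raise ValueError("true_carbs must be > 0")
        if not self.announced_carbs > 0:
            raise ValueError("announced_carbs must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")

    @property
    def carb_rate(self) -> float:
        """Gut delivery rate, mg/min."""
        return 1000.0 * self.true_carbs / self.duration


@dataclass
class Scenario:
    """An ordered meal timetable over ``days`` simulated days."""

    days: int
    meals: list[MealEvent] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        times = [m.start_time for m in self.meals]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("meals must be strictly increasing in start_time")

    @property
    def horizon_min(self) -> float:
        return self.days * MINUTES_PER_DAY


def generate_scenario(days: int, rng_seed: int,
                      protocol: MealProtocol | None = None) -> Scenario:
    """Draw a meal scenario under the daily three-meal protocol.

    Per day and nominal meal, the start time is Normal(nominal, time StD),
    the true size Normal(nominal, CV * nominal) truncated positive, and the
    announced size the true size times a uniform misestimation multiplier.
    Jittered meals that overlap (or leave the day) are redrawn a bounded
    number of times. Deterministic given ``rng_seed``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    protocol = protocol or MealProtocol()
    rng = np.random.default_rng(rng_seed)
    meals: list[MealEvent] = []

    for day in range(days):
        day_start = day * MINUTES_PER_DAY
        prev_end = meals[-1].start_time + meals[-1].duration if meals else -np.inf
        for nominal_t, nominal_c in zip(protocol.nominal_times_min,
                                        protocol.nominal_carbs_g):
            for attempt in range(protocol.max_redraws + 1):
                t = day_start + float(rng.normal(nominal_t, protocol.time_std_min))
                # meals stay inside their own day and in order
                if t > prev_end and \
                        day_start <= t <= day_start + MINUTES_PER_DAY - protocol.meal_duration_min:
                    break
            else:
                raise RuntimeError(
                    f"could not place meal at nominal t={nominal_t} on day {day} "
                    f"after {protocol.max_redraws} redraws")
            size = 0.0
            while size <= 0.0:
                size = float(rng.normal(nominal_c, protocol.size_cv * nominal_c))
            lo, hi = protocol.misestimation_range
            announced = size * float(rng.uniform(lo, hi))
            meals.append(MealEvent(start_time=t, true_carbs=size,
                                   announced_carbs=announced,
                                   duration=protocol.meal_duration_min))
            prev_end = t + protocol.meal_duration_min
    return Scenario(days=days, meals=meals, rng_seed=rng_seed)
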