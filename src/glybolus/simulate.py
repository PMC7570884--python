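"""Closed-loop simulation: virtual patient + CGM sensor + meal scenario +
bolus policy, integrated minute by minute.

Any bolus policy is a callable mapping an :class:`~glybolus.agent.AgentState`
to :class:`~glybolus.agent.ActionGains`; the standard bolus calculator is the
fixed gain vector [1, 1, 1]. Because both the calculator baseline and the
learning agent run through this single engine (and the sensor noise stream is
consumed on the sampling grid, independent of dosing), two policies evaluated
on the same seed consume identical scenarios and sensor noise, and a policy
pinned at gains [1, 1, 1] reproduces the calculator trace bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import ActionGains, AgentState, build_state, gains_to_bolus
from .config import SCHEMA_VERSION, SafetyConstraint, SimConfig
from .patient import (
    CGMSensor,
    CGMTrace,
    PatientParams,
    basal_rate,
    fasting_state,
    step,
)
from .replay import Transition
from .reward import POSTPRANDIAL_WINDOW_MIN, meal_reward
from .scenario import MealEvent, Scenario
from .therapy import BolusRecord, TherapyParams, compute_iob, sbc_dose

__all__ = ["FixedGainsPolicy", "AgentPolicy", "SimulationLog",
           "apply_safety_constraint", "run_closed_loop"]

SBC_GAINS = ActionGains(1.0, 1.0, 1.0)


class FixedGainsPolicy:
    """Constant-gain policy; [1, 1, 1] is the standard bolus calculator."""

    def __init__(self, gains: ActionGains = SBC_GAINS) -> None:
        self.gains = gains

    def __call__(self, state: AgentState) -> ActionGains:
        return self.gains


class AgentPolicy:
    """Wraps a DDPG agent as a policy, optionally exploring."""

    def __init__(self, agent, explore_noise_std: float = 0.0,
                 rng: np.random.Generator | None = None) -> None:
        self.agent = agent
        self.explore_noise_std = explore_noise_std
        self.rng = rng

    def __call__(self, state: AgentState) -> ActionGains:
        return self.agent.act(state, self.explore_noise_std, self.rng)


def apply_safety_constraint(proposed_dose: float, sbc: float, cgm_now: float,
                            c: SafetyConstraint) -> float:
    """Restrict a proposed dose relative to the calculator dose.

    Above the hyperglycemia threshold the effective gain may not fall below
    1 (dose >= calculator); below the hypoglycemia threshold it may not
    exceed 1 (dose <= calculator); in between the dose passes unchanged.
    """
    if proposed_dose < 0 or sbc < 0:
        raise ValueError("doses must be >= 0")
    if not c.enabled:
        return proposed_dose
    if cgm_now > c.hyper_threshold:
        return max(proposed_dose, sbc)
    if cgm_now < c.hypo_threshold:
        return min(proposed_dose, sbc)
    return proposed_dose


@dataclass
class BolusEvent:
    time: float
    dose: float            # executed, IU
    proposed_dose: float   # policy's dose before the safety constraint
    sbc_reference: float   # calculator dose on the same state
    gains: ActionGains


@dataclass
class SimulationLog:
    """Everything one closed-loop run produced."""

    cgm: CGMTrace
    plasma: np.ndarray                 # true glucose at the CGM times
    boluses: list[BolusEvent]
    meals: list[MealEvent]
    transitions: list[Transition]
    basal_mU_min: float
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-sample log (CGM grid; bolus/meal columns on their rows)."""
        n = len(self.cgm)
        df = pd.DataFrame({
            "time_min": self.cgm.times,
            "cgm_mgdl": self.cgm.values,
            "plasma_mgdl": self.plasma,
            "bolus_IU": np.zeros(n),
            "basal_mU_min": np.full(n, self.basal_mU_min),
            "true_carbs_g": np.zeros(n),
            "announced_carbs_g": np.zeros(n),
        })
        spacing = self.cgm.spacing
        for b in self.boluses:
            i = int(np.searchsorted(self.cgm.times, b.time, side="right")) - 1
            if 0 <= i < n:
                df.loc[i, "bolus_IU"] += b.dose
        for m in self.meals:
            i = int(np.searchsorted(self.cgm.times, m.start_time,
                                    side="right")) - 1
            if 0 <= i < n:
                df.loc[i, "true_carbs_g"] += m.true_carbs
                df.loc[i, "announced_carbs_g"] += m.announced_carbs
        df.attrs["schema_version"] = SCHEMA_VERSION
        df.attrs["cgm_spacing_min"] = spacing
        return df


def _restricted_gains(gains: ActionGains, proposed: float, executed: float,
                      clip) -> ActionGains:
    """Executed action after a constraint changed the dose: rescale the gain
    vector by the dose ratio (clipped back to range). The gain-to-dose map is
    not invertible, so this is the closest representable executed action."""
    if executed == proposed or proposed <= 0:
        return gains
    g = clip(gains.as_array() * (executed / proposed))
    return ActionGains(*[float(v) for v in g])


def run_closed_loop(params: PatientParams, therapy: TherapyParams,
                    scenario: Scenario, policy, seed: int,
                    sim: SimConfig | None = None,
                    constraint: SafetyConstraint | None = None,
                    on_transition=None) -> SimulationLog:
    """Simulate a full scenario under one bolus policy.

    The patient starts at fasting equilibrium at midnight of day 0 under the
    subject's steady-state basal infusion. CGM is sampled every
    ``sim.cgm_period_min`` minutes; boluses are delivered at (rounded) meal
    start. A meal transition <s, a, r, s'> completes when the next meal is
    reached (or, for the final meal, at the end of its 5-h window, with the
    successor state taken there); ``on_transition`` is invoked at completion,
    which lets a trainer update the acting policy mid-run.
    """
    sim = sim or SimConfig()
    if sim.dt_min != 1.0:
        raise NotImplementedError("the minute-grid engine requires dt=1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    sensor = CGMSensor(sim.sensor, rng)
    basal = basal_rate(params)
    state = fasting_state(params)
    period = int(sim.cgm_period_min)
    L = sim.history_length

    meals = list(scenario.meals)
    last_window_end = (meals[-1].start_time + POSTPRANDIAL_WINDOW_MIN
                       if meals else 0.0)
    horizon = int(np.ceil(max(scenario.horizon_min, last_window_end + period)))

    times: list[float] = []
    cgm_vals: list[float] = []
    plasma: list[float] = []
    boluses: list[BolusEvent] = []
    transitions: list[Transition] = []
    last_bolus: BolusRecord | None = None

    # carb delivery schedule on the minute grid
    meal_idx = 0
    active: list[tuple[int, int, float]] = []  # (start_min, end_min, rate)
    pending: tuple[AgentState, ActionGains, MealEvent] | None = None

    def trace() -> CGMTrace:
        return CGMTrace(np.array(times), np.array(cgm_vals))

    def finalize(next_meal: MealEvent | None, tr: CGMTrace) -> None:
        nonlocal pending
        if pending is None:
            return
        s_prev, a_prev, m_prev = pending
        if next_meal is not None:
            r = meal_reward(tr, m_prev.start_time, next_meal.start_time)
            s_next = build_state(tr, next_meal,
                                 compute_iob(last_bolus, next_meal.start_time,
                                             therapy), L)
        else:
            r = meal_reward(tr, m_prev.start_time, None)
            end = m_prev.start_time + POSTPRANDIAL_WINDOW_MIN
            pseudo = MealEvent(start_time=end, true_carbs=1e-9,
                               announced_carbs=1e-9, duration=1.0)
            s_next = build_state(tr, pseudo,
                                 compute_iob(last_bolus, end, therapy), L)
            s_next = AgentState(cgm_history=s_next.cgm_history,
                                announced_carbs=0.0,
                                time_sin=s_next.time_sin,
                                time_cos=s_next.time_cos,
                                iob=s_next.iob, cgm_now=s_next.cgm_now)
        t = Transition(state=s_prev, action=a_prev, reward=r,
                       next_state=s_next, time=m_prev.start_time)
        transitions.append(t)
        pending = None
        if on_transition is not None:
            on_transition(t)

    clipper = getattr(policy, "agent", None)
    clip = (clipper.clip_gains if clipper is not None
            else lambda g: np.clip(g, 0.2, 2.0))

    for minute in range(horizon + 1):
        t = float(minute)
        # sensing on the CGM grid
        if minute % period == 0:
            times.append(t)
            cgm_vals.append(sensor.read(state.plasma_glucose))
            plasma.append(state.plasma_glucose)

        bolus_iu = 0.0
        while meal_idx < len(meals) and round(meals[meal_idx].start_time) == minute:
            meal = meals[meal_idx]
            tr = trace()
            finalize(meal, tr)
            iob = compute_iob(last_bolus, meal.start_time, therapy)
            s = build_state(tr, meal, iob, L)
            gains = policy(s)
            proposed = gains_to_bolus(meal.announced_carbs, s.cgm_now, iob,
                                      gains, therapy)
            sbc_ref = sbc_dose(meal.announced_carbs, s.cgm_now, iob, therapy)
            dose = proposed
            if constraint is not None and constraint.enabled:
                dose = apply_safety_constraint(proposed, sbc_ref, s.cgm_now,
                                               constraint)
            executed_gains = _restricted_gains(gains, proposed, dose, clip)
            boluses.append(BolusEvent(time=t, dose=dose,
                                      proposed_dose=proposed,
                                      sbc_reference=sbc_ref,
                                      gains=executed_gains))
            if dose > 0:
                last_bolus = BolusRecord(time=meal.start_time, dose=dose)
            bolus_iu += dose
            pending = (s, executed_gains, meal)
            active.append((minute, minute + int(round(meal.duration)),
                           meal.carb_rate))
            meal_idx += 1

        if minute == horizon:
            break
        carb_rate = sum(rate for lo, hi, rate in active if lo <= minute < hi)
        active = [(lo, hi, rate) for lo, hi, rate in active if hi > minute]
        state = step(state, params, basal, bolus_iu, carb_rate, dt=1.0)

    finalize(None, trace())
    return SimulationLog(cgm=trace(), plasma=np.array(plasma),
                         boluses=boluses, meals=meals,
                         transitions=transitions, basal_mU_min=basal,
                         seed=seed)
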