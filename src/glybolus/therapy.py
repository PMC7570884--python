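"""Standard bolus calculator (SBC) and insulin-on-board bookkeeping.

The calculator is the fixed-parameter formula used in pump/CGM therapy:

    bolus = CHO / ICR + (G - G_T) / ISF - IOB

with ICR the insulin-to-carbohydrate ratio (g/IU), ISF the insulin
sensitivity factor (mg/dL per IU), G_T the target glucose and IOB the
residual action of the most recent bolus, decaying linearly to zero over
``t_iob`` minutes. Negative formula values are clamped to zero: insulin
cannot be withdrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import (
    DEFAULT_T_IOB,
    DEFAULT_TARGET_GLUCOSE,
    THERAPY_REFERENCE_GLUCOSE,
)
from .patient import PatientParams

__all__ = ["TherapyParams", "BolusRecord", "compute_iob", "sbc_dose",
           "derive_therapy"]


@dataclass(frozen=True)
class TherapyParams:
    """Fixed (non-time-varying) clinical therapy settings for one subject."""

    icr: float                        # g/IU
    isf: float                        # mg/dL per IU
    target_glucose: float = DEFAULT_TARGET_GLUCOSE  # mg/dL
    t_iob: float = DEFAULT_T_IOB      # min
    correction_portion: float = 1.0   # multiplier on the correction term

    def __post_init__(self) -> None:
        for name in ("icr", "isf", "target_glucose", "t_iob"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 90.0 <= self.target_glucose <= 140.0:
            raise ValueError("target_glucose must be within [90, 140] mg/dL")


@dataclass(frozen=True)
class BolusRecord:
    """A delivered bolus: time (min) and dose (IU)."""

    time: float
    dose: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


def compute_iob(previous: BolusRecord | None, now: float,
                therapy: TherapyParams) -> float:
    """Insulin on board from the most recent bolus, linear decay.

    ``IOB = dose * max(0, 1 - elapsed / t_iob)``; zero when no bolus has
    been delivered yet. Only the single most recent bolus is counted.
    """
    if previous is None:
        return 0.0
    elapsed = now - previous.time
    if elapsed < 0:
        raise ValueError("now must be >= previous bolus time")
    return previous.dose * max(0.0, 1.0 - elapsed / therapy.t_iob)


def compute_iob_stacked(history: list[BolusRecord], now: float,
                        therapy: TherapyParams) -> float:
    """Optional stacked variant summing all still-active boluses (off by
    default everywhere; the single-bolus form above is the standard)."""
    return sum(compute_iob(b, now, therapy) for b in history
               if 0.0 <= now - b.time < therapy.t_iob)


def sbc_dose(announced_carbs: float, cgm_now: float, iob: float,
             therapy: TherapyParams) -> float:
    """Standard bolus calculator dose, IU, clamped at zero."""
    if announced_carbs < 0:
        raise ValueError("announced_carbs must be >= 0")
    if not 40.0 <= cgm_now <= 400.0:
        raise ValueError("cgm_now must lie in the sensor range [40, 400]")
    dose = (announced_carbs / therapy.icr
            + therapy.correction_portion * (cgm_now - therapy.target_glucose) / therapy.isf
            - iob)
    return max(0.0, dose)


def derive_therapy(params: PatientParams,
                   target_glucose: float = DEFAULT_TARGET_GLUCOSE,
                   t_iob: float = DEFAULT_T_IOB) -> TherapyParams:
    """Derive fixed therapy settings from a subject's nominal physiology.

    ISF is the first-order dose response of the surrogate model: one IU
    produces an integrated remote-insulin exposure of
    ``(p3/p2) * 1000 / (V_I ke)`` which, at a reference glucose, lowers
    glucose by about ``SI (p3/p2) (1000/(V_I ke)) G_ref`` mg/dL. ICR follows
    from converting that disposal back to grams of carbohydrate through the
    distribution volume and bioavailability. These settings deliberately
    ignore the intra-day sensitivity sinusoid and announcement errors —
    exactly the fixed-parameter clinical practice the adaptive agent is
    meant to improve on.
    """
    exposure = (params.p3 / params.p2) * 1000.0 / (
        params.insulin_distribution_volume * params.insulin_elimination_ke)
    isf = (params.insulin_sensitivity_nominal * exposure
           * THERAPY_REFERENCE_GLUCOSE)
    disposal_mg = isf * params.glucose_distribution_volume * params.body_weight
    icr = disposal_mg / 1000.0 / params.carb_bioavailability
    return TherapyParams(icr=icr, isf=isf, target_glucose=target_glucose,
                         t_iob=t_iob)
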