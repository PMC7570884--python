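"""Surrogate virtual type-1-diabetes patient.

The model is a minimal-model-family ODE with seven compartments:

* plasma glucose ``G`` (mg/dL):
  ``dG/dt = -p1 (G - Gb) - SI(t) X G + Ra(t) / (V_G BW)``
* remote insulin action ``X`` (1/min):
  ``dX/dt = -p2 X + p3 (I - Ib)``
* a two-compartment subcutaneous insulin chain ``S1 -> S2`` (mU) with time
  constant ``tmax`` feeding plasma insulin ``I`` (mU/L), eliminated at ``ke``
* a two-compartment gut chain ``Q1 -> Q2`` (mg) with time constant
  ``gut_tmax``; glucose appearance ``Ra = f_bio Q2 / gut_tmax``; meal carbs
  enter ``Q1`` at a constant rate over the meal duration.

``SI(t)`` is the nominal insulin-sensitivity multiplier modulated by a
24-h sinusoid (amplitude 30% by default) emulating intra-day variability.
Integration is fixed-step RK4 (default 1 min) for bit-reproducibility.

This surrogate deliberately trades physiological fidelity for transparency:
it reproduces the qualitative shape of postprandial excursions and the
basal/bolus dose-response, not any licensed simulator's quantitative output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace, asdict

import numpy as np

from .config import (
    ADOLESCENT_MODIFIERS,
    CGM_RANGE,
    COHORT_GEOMETRIC_CV,
    NOMINAL_ADULT,
    SensorConfig,
)

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440.0

__all__ = [
    "PatientParams",
    "PatientState",
    "CGMTrace",
    "CGMSensor",
    "sensitivity_multiplier",
    "basal_rate",
    "fasting_state",
    "step",
    "make_cohort",
]


@dataclass(frozen=True)
class PatientParams:
    """Parameters of one virtual subject. See module docstring for the model."""

    basal_glucose: float            # mg/dL
    glucose_effectiveness: float    # 1/min (p1)
    p2: float                       # 1/min
    p3: float                       # 1/min per (mU/L)
    insulin_sensitivity_nominal: float  # dimensionless
    glucose_distribution_volume: float  # dL/kg
    body_weight: float              # kg
    insulin_absorption_tmax: float  # min
    insulin_elimination_ke: float   # 1/min
    insulin_distribution_volume: float  # L
    gut_tmax: float                 # min
    carb_bioavailability: float     # (0, 1]
    basal_plasma_insulin: float     # mU/L
    sensitivity_variation_amplitude: float = 0.30
    sensitivity_variation_phase: float = 0.0  # min
    label: str = "subject"

    def __post_init__(self) -> None:
        positive = (
            "basal_glucose", "glucose_effectiveness", "p2",
            "insulin_sensitivity_nominal", "glucose_distribution_volume",
            "body_weight", "insulin_absorption_tmax", "insulin_elimination_ke",
            "insulin_distribution_volume", "gut_tmax", "basal_plasma_insulin",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        # p3 = 0 is allowed: a fully insulin-insensitive probe subject
        if self.p3 < 0:
            raise ValueError("p3 must be nonnegative")
        if not 0 < self.carb_bioavailability <= 1:
            raise ValueError("carb_bioavailability must be in (0, 1]")
        if not 0 <= self.sensitivity_variation_amplitude < 1:
            raise ValueError("sensitivity_variation_amplitude must be in [0, 1)")

    @classmethod
    def nominal_adult(cls, **overrides) -> "PatientParams":
        return cls(**{**NOMINAL_ADULT, "label": "adult-nominal", **overrides})

    @classmethod
    def nominal_adolescent(cls, **overrides) -> "PatientParams":
        values = {**NOMINAL_ADULT, **ADOLESCENT_MODIFIERS,
                  "label": "adolescent-nominal", **overrides}
        return cls(**values)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatientState:
    """Compartment state of one subject at ``clock_time`` minutes."""

    plasma_glucose: float       # mg/dL
    remote_insulin_action: float  # 1/min
    sc_insulin_depot_1: float   # mU
    sc_insulin_depot_2: float   # mU
    plasma_insulin: float       # mU/L
    gut_compartment_1: float    # mg
    gut_compartment_2: float    # mg
    clock_time: float = 0.0     # min since scenario start

    _FIELDS = ("plasma_glucose", "remote_insulin_action", "sc_insulin_depot_1",
               "sc_insulin_depot_2", "plasma_insulin", "gut_compartment_1",
               "gut_compartment_2")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    def validate(self) -> None:
        for name in self._FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise FloatingPointError(f"non-finite compartment: {name}={v!r}")
        if not self.plasma_glucose > 0:
            raise FloatingPointError("plasma_glucose must stay positive")


@dataclass
class CGMTrace:
    """Uniformly sampled CGM record (defaults: 5-min spacing, mg/dL)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1:
            d = np.diff(self.times)
            if not np.allclose(d, d[0]):
                raise ValueError("CGM samples must be uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.nan

    def window(self, start: float, stop: float) -> "CGMTrace":
        """Samples with start < t <= stop."""
        mask = (self.times > start) & (self.times <= stop)
        return CGMTrace(self.times[mask], self.values[mask])

    def __len__(self) -> int:
        return len(self.times)


def sensitivity_multiplier(t: float, params: PatientParams) -> float:
    """Sinusoidal intra-day insulin-sensitivity modulation, 24-h period.

    Returns ``1 + a sin(2 pi (t - phase) / 1440)`` so a 30% amplitude spans
    exactly [0.7, 1.3] over a day.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    a = params.sensitivity_variation_amplitude
    return 1.0 + a * math.sin(
        2.0 * math.pi * (t - params.sensitivity_variation_phase) / MINUTES_PER_DAY
    )


def basal_rate(params: PatientParams) -> float:
    """Constant basal insulin infusion (mU/min) solving the fasting steady state.

    At steady state the subcutaneous chain passes the infusion through
    unchanged, so plasma insulin settles at ``u_b / (ke V_I)``; choosing
    ``u_b = Ib ke V_I`` pins plasma insulin at the basal set point, which
    zeroes remote insulin action and leaves glucose at ``basal_glucose``.
    """
    return (params.basal_plasma_insulin * params.insulin_elimination_ke
            * params.insulin_distribution_volume)


def fasting_state(params: PatientParams, clock_time: float = 0.0) -> PatientState:
    """Equilibrium state under the basal infusion of :func:`basal_rate`."""
    ub = basal_rate(params)
    s_eq = ub * params.insulin_absorption_tmax
    return PatientState(
        plasma_glucose=params.basal_glucose,
        remote_insulin_action=0.0,
        sc_insulin_depot_1=s_eq,
        sc_insulin_depot_2=s_eq,
        plasma_insulin=params.basal_plasma_insulin,
        gut_compartment_1=0.0,
        gut_compartment_2=0.0,
        clock_time=clock_time,
    )


def _deriv(y: tuple, t: float, p: PatientParams, insulin_in: float,
           carb_in: float) -> tuple:
    """Right-hand side. y packs the seven compartments; rates in per-minute."""
    G, X, S1, S2, I, Q1, Q2 = y
    tmax = p.insulin_absorption_tmax
    gtmax = p.gut_tmax
    si = p.insulin_sensitivity_nominal * sensitivity_multiplier(t, p)
    ra = p.carb_bioavailability * Q2 / gtmax  # mg/min
    dG = (-p.glucose_effectiveness * (G - p.basal_glucose)
          - si * X * G
          + ra / (p.glucose_distribution_volume * p.body_weight))
    dX = -p.p2 * X + p.p3 * (I - p.basal_plasma_insulin)
    dS1 = insulin_in - S1 / tmax
    dS2 = (S1 - S2) / tmax
    dI = S2 / (tmax * p.insulin_distribution_volume) - p.insulin_elimination_ke * I
    dQ1 = carb_in - Q1 / gtmax
    dQ2 = (Q1 - Q2) / gtmax
    return (dG, dX, dS1, dS2, dI, dQ1, dQ2)


def step(state: PatientState, params: PatientParams, basal: float,
         bolus_iu: float = 0.0, carb_rate: float = 0.0,
         dt: float = 1.0) -> PatientState:
    """Advance the patient one fixed RK4 step of ``dt`` minutes.

    Parameters
    ----------
    basal : float
        Continuous insulin infusion, mU/min.
    bolus_iu : float
        Bolus delivered at the start of this step, IU (added to the first
        subcutaneous depot as an impulse).
    carb_rate : float
        Carbohydrate delivery into the gut, mg/min, held constant over the step.
    """
    if not 0 < dt <= 5.0:
        raise ValueError("dt must be in (0, 5] minutes")
    for v, name in ((basal, "basal"), (bolus_iu, "bolus_iu"),
                    (carb_rate, "carb_rate")):
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite input: {name}={v!r}")
    state.validate()

    t = state.clock_time
    y = (state.plasma_glucose, state.remote_insulin_action,
         state.sc_insulin_depot_1 + 1000.0 * bolus_iu,  # IU -> mU impulse
         state.sc_insulin_depot_2, state.plasma_insulin,
         state.gut_compartment_1, state.gut_compartment_2)

    k1 = _deriv(y, t, params, basal, carb_rate)
    y2 = tuple(yi + 0.5 * dt * ki for yi, ki in zip(y, k1))
    k2 = _deriv(y2, t + 0.5 * dt, params, basal, carb_rate)
    y3 = tuple(yi + 0.5 * dt * ki for yi, ki in zip(y, k2))
    k3 = _deriv(y3, t + 0.5 * dt, params, basal, carb_rate)
    y4 = tuple(yi + dt * ki for yi, ki in zip(y, k3))
    k4 = _deriv(y4, t + dt, params, basal, carb_rate)

    out = [yi + dt / 6.0 * (a + 2 * b + 2 * c + d)
           for yi, a, b, c, d in zip(y, k1, k2, k3, k4)]
    for i, name in enumerate(PatientState._FIELDS):
        if out[i] < 0.0:
            if out[i] < -1e-9:
                logger.warning("integrator undershoot: %s=%.3e clipped to 0",
                               name, out[i])
            out[i] = 0.0

    new = PatientState(*out, clock_time=t + dt)
    new.validate()
    return new


class CGMSensor:
    """CGM error model: AR(1) additive noise, clamped to the sensor range.

    The stationary marginal StD equals ``noise_std``; successive errors have
    lag-1 autocorrelation ``ar_coeff``. With ``noise_std=0`` the sensor is an
    exact (clamped) pass-through.
    """

    def __init__(self, config: SensorConfig | None = None,
                 rng: np.random.Generator | None = None) -> None:
        self.config = config or SensorConfig()
        self.rng = rng if rng is not None else np.random.default_rng()
        self._err = 0.0
        if self.config.noise_std > 0:
            # start from the stationary distribution
            self._err = float(self.rng.normal(0.0, self.config.noise_std))

    def read(self, plasma_glucose: float) -> float:
        if not plasma_glucose > 0:
            raise ValueError("plasma_glucose must be positive")
        c = self.config
        if c.noise_std > 0:
            innov_std = c.noise_std * math.sqrt(1.0 - c.ar_coeff ** 2)
            self._err = c.ar_coeff * self._err + float(
                self.rng.normal(0.0, innov_std))
        lo, hi = CGM_RANGE
        return float(min(max(plasma_glucose + self._err, lo), hi))


def cgm_read(plasma_glucose: float, rng: np.random.Generator,
             config: SensorConfig | None = None) -> float:
    """One-shot stateless CGM reading (fresh sensor, stationary error draw)."""
    return CGMSensor(config, rng).read(plasma_glucose)


_PERTURBED_FIELDS = (
    "glucose_effectiveness", "p2", "p3", "insulin_sensitivity_nominal",
    "glucose_distribution_volume", "body_weight", "insulin_absorption_tmax",
    "insulin_elimination_ke", "insulin_distribution_volume", "gut_tmax",
    "basal_plasma_insulin",
)


def make_cohort(n_adults: int, n_adolescents: int, rng_seed: int,
                geometric_cv: float = COHORT_GEOMETRIC_CV) -> list[PatientParams]:
    """Sample a virtual cohort by log-normal perturbation of the nominals.

    Returns ``1 + n_adults + n_adolescents`` parameter sets: the unperturbed
    nominal adult (the "average subject" used for population training) first,
    then the adults, then the adolescents. Basal glucose is perturbed mildly
    (5% of the geometric CV applied normally); each subject gets a uniform
    random phase for the sensitivity sinusoid. Deterministic given the seed.
    """
    if n_adults < 0 or n_adolescents < 0:
        raise ValueError("cohort counts must be >= 0")
    rng = np.random.default_rng(rng_seed)
    sigma = math.sqrt(math.log1p(geometric_cv ** 2))
    cohort = [PatientParams.nominal_adult(label="average")]

    for group, nominal, n in (
        ("adult", PatientParams.nominal_adult(), n_adults),
        ("adolescent", PatientParams.nominal_adolescent(), n_adolescents),
    ):
        for i in range(n):
            overrides = {}
            for name in _PERTURBED_FIELDS:
                mult = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                overrides[name] = getattr(nominal, name) * mult
            overrides["basal_glucose"] = nominal.basal_glucose * float(
                1.0 + 0.3 * geometric_cv * rng.standard_normal())
            # zero CV means an exact copy of the nominal, phase included
            overrides["sensitivity_variation_phase"] = float(
                rng.uniform(0.0, MINUTES_PER_DAY)) if geometric_cv > 0 else \
                nominal.sensitivity_variation_phase
            overrides["label"] = f"{group}-{i + 1:02d}"
            cohort.append(replace(nominal, **overrides))
    return cohort
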