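"""Central configuration: every surrogate-model constant and training
hyper-parameter default lives here, not scattered through the code.

Units are stated per field. The virtual-patient constants parameterize the
minimal-model surrogate defined in :mod:`glybolus.patient`; they were chosen
once for clinical plausibility of the standard-bolus-calculator baseline and
are frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

SCHEMA_VERSION = 1

#: CGM sampling period, min.
CGM_PERIOD_MIN = 5.0
#: CGM sensor reporting range, mg/dL.
CGM_RANGE = (40.0, 400.0)

#: Glycemic target band boundaries, mg/dL (hypo / hyper thresholds).
HYPO_THRESHOLD = 70.0
HYPER_THRESHOLD = 180.0


@dataclass
class SensorConfig:
    """CGM error model: first-order autocorrelated additive noise."""

    noise_std: float = 5.0      # mg/dL, stationary marginal StD
    ar_coeff: float = 0.7       # lag-1 autocorrelation


@dataclass
class MealProtocol:
    """Daily three-meal pattern with the stochastic variability applied to it.

    Times are minutes after midnight; carbs in grams. Meal times get Gaussian
    jitter (StD ``time_std_min``), sizes a Gaussian with coefficient of
    variation ``size_cv``, and the announced (patient-estimated) carb content
    is the true content times a uniform draw over ``misestimation_range``.
    """

    nominal_times_min: tuple[float, ...] = (420.0, 840.0, 1260.0)  # 7am, 2pm, 9pm
    nominal_carbs_g: tuple[float, ...] = (70.0, 110.0, 90.0)
    meal_duration_min: float = 15.0
    time_std_min: float = 30.0
    size_cv: float = 0.10
    misestimation_range: tuple[float, float] = (0.7, 1.1)
    max_redraws: int = 10


@dataclass
class SimConfig:
    """Numerical integration and sensing settings for the closed loop."""

    dt_min: float = 1.0                 # fixed RK4 step, min
    cgm_period_min: float = CGM_PERIOD_MIN
    sensor: SensorConfig = field(default_factory=SensorConfig)
    history_length: int = 12            # L: CGM samples in the agent state
    warmup_min: float = 0.0             # extra lead-in before the first day


@dataclass
class AgentConfig:
    """DDPG actor-critic hyper-parameters.

    The actor and critic are three-hidden-layer fully connected networks.
    Gains are squashed onto ``gain_range`` with an affine tanh head,
    g = c + h*tanh(z), so a zero pre-activation yields the mid-range gain.
    """

    history_length: int = 12
    hidden: tuple[int, ...] = (64, 64, 64)
    actor_lr: float = 1e-4
    critic_lr: float = 1e-3
    critic_weight_decay: float = 1e-2
    gamma: float = 0.9
    tau: float = 0.01
    target_period: int = 1
    batch_size: int = 32
    gain_range: tuple[float, float] = (0.2, 2.0)
    # Fixed affine standardization of the state vector (portable across subjects)
    cgm_center: float = 140.0
    cgm_scale: float = 60.0
    carb_scale: float = 100.0
    iob_scale: float = 10.0


@dataclass
class ReplayConfig:
    """Proportional prioritized replay settings."""

    capacity: int = 100_000
    epsilon: float = 0.01   # priority floor offset on |TD error|
    alpha: float = 0.6      # prioritization exponent (0 = uniform)
    beta_start: float = 0.4  # importance-weight exponent at start of training
    beta_end: float = 1.0
    anneal_beta: bool = True


@dataclass
class TrainConfig:
    """Settings for one training phase (population or personalized)."""

    phase: str = "population"           # "population" | "personalized"
    training_days: int = 180
    explore_noise_std: float = 0.3      # population default; 0.1 personalized
    updates_per_transition: int = 5     # gradient steps per stored meal transition
    actor_delay: int = 1                # actor updated every k-th critic update
    convergence_window: int = 50        # critic-loss moving-average window
    convergence_rtol: float = 1e-3
    min_transitions: int = 32           # replay warm-up before updates start
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.training_days < 0:
            raise ValueError("training_days must be >= 0")
        if self.explore_noise_std < 0:
            raise ValueError("explore_noise_std must be >= 0")
        if self.phase not in ("population", "personalized"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class SafetyConstraint:
    """Dose restriction relative to the standard bolus calculator.

    In hyperglycemia the executed dose may not fall below the calculator
    dose (effective gain >= 1); in hypoglycemia it may not exceed it
    (effective gain <= 1).
    """

    hyper_threshold: float = HYPER_THRESHOLD
    hypo_threshold: float = HYPO_THRESHOLD
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.hypo_threshold < self.hyper_threshold:
            raise ValueError("hypo_threshold must be below hyper_threshold")


# ---------------------------------------------------------------------------
# Surrogate virtual-patient nominal constants
# ---------------------------------------------------------------------------

#: Nominal adult parameters for the minimal-model surrogate (see patient.py).
#: These are invented, documented constants standing in for a full
#: physiological simulator; see docs/methods.md for the calibration rationale.
NOMINAL_ADULT = dict(
    basal_glucose=130.0,             # mg/dL fasting set point
    glucose_effectiveness=0.004,     # 1/min, insulin-independent disposal (p1)
    p2=0.02,                         # 1/min, remote-insulin decay
    p3=1.5e-5,                       # 1/min per (mU/L), remote-insulin gain
    insulin_sensitivity_nominal=1.0,  # dimensionless multiplier on insulin action
    glucose_distribution_volume=1.6,  # dL/kg
    body_weight=70.0,                # kg
    insulin_absorption_tmax=55.0,    # min, subcutaneous absorption time constant
    insulin_elimination_ke=0.14,     # 1/min, plasma insulin elimination
    insulin_distribution_volume=12.0,  # L
    gut_tmax=40.0,                   # min, gut transit time constant
    carb_bioavailability=0.8,        # fraction of carbs reaching plasma
    basal_plasma_insulin=10.0,       # mU/L, fasting plasma insulin set point
    sensitivity_variation_amplitude=0.30,
    sensitivity_variation_phase=0.0,  # min
)

#: Multiplicative / override modifiers defining the adolescent nominal subject
#: relative to the adult: lower insulin sensitivity, lighter body, larger
#: intra-day sensitivity swings. A surrogate-only contrast.
ADOLESCENT_MODIFIERS = dict(
    insulin_sensitivity_nominal=0.6,
    body_weight=50.0,
    sensitivity_variation_amplitude=0.35,
)

#: Geometric coefficient of variation of the log-normal inter-subject
#: parameter perturbation used by make_cohort.
COHORT_GEOMETRIC_CV = 0.15

#: Reference glucose used when deriving therapy parameters from physiology.
THERAPY_REFERENCE_GLUCOSE = 140.0
DEFAULT_TARGET_GLUCOSE = 120.0   # mg/dL
DEFAULT_T_IOB = 240.0            # min


def config_hash(*objs) -> str:
    """Short stable hash of dataclass configs, for artifact provenance."""
    import hashlib
    import json

    payload = json.dumps([asdict(o) if hasattr(o, "__dataclass_fields__") else o
                          for o in objs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
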