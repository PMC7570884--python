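"""DDPG actor-critic agent over bolus-calculator gains.

The agent observes, at each meal, the recent CGM history, the announced
carbohydrate content, the time of day and the insulin on board, and emits a
three-component gain vector ``[g_icr, g_isf, g_iob]`` in [0.2, 2] that
rescales the three terms of the standard bolus calculator:

    dose = g_icr * CHO/ICR + g_isf * (G - G_T)/ISF - g_iob * IOB

With all gains at 1 the agent reproduces the calculator exactly. The critic
learns the meal-level action value by bootstrapped TD regression against
slowly tracking target networks; the actor ascends the critic's value of its
own action (the deterministic policy gradient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AgentConfig
from .networks import MLP, Adam
from .patient import CGMTrace
from .replay import SampledBatch
from .scenario import MealEvent
from .therapy import TherapyParams, sbc_dose

__all__ = ["AgentState", "ActionGains", "build_state", "gains_to_bolus",
           "DDPGAgent"]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class AgentState:
    """Observation at a meal: CGM history (oldest first), announced carbs,
    encoded clock time and insulin on board."""

    cgm_history: tuple[float, ...]   # mg/dL, length L
    announced_carbs: float           # g
    time_sin: float
    time_cos: float
    iob: float                       # IU
    cgm_now: float                   # latest CGM reading, mg/dL (convenience)

    def __post_init__(self) -> None:
        vals = (*self.cgm_history, self.announced_carbs, self.time_sin,
                self.time_cos, self.iob)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("agent state contains non-finite values")


@dataclass(frozen=True)
class ActionGains:
    """Bolus-calculator gain vector, each component within the gain range."""

    g_icr: float
    g_isf: float
    g_iob: float

    def as_array(self) -> np.ndarray:
        return np.array([self.g_icr, self.g_isf, self.g_iob])


def build_state(trace: CGMTrace, meal: MealEvent, iob: float,
                history_length: int = 12) -> AgentState:
    """Assemble the agent state at a meal from the CGM record so far.

    Uses the last ``history_length`` CGM samples at or before the meal start
    (oldest to newest). Raises when the warm-up history is too short.
    """
    mask = trace.times <= meal.start_time
    values = trace.values[mask]
    if len(values) < history_length:
        raise ValueError(
            f"need {history_length} CGM samples before the meal, "
            f"have {len(values)}")
    hist = values[-history_length:]
    clock = meal.start_time % MINUTES_PER_DAY
    angle = 2.0 * math.pi * clock / MINUTES_PER_DAY
    return AgentState(
        cgm_history=tuple(float(v) for v in hist),
        announced_carbs=meal.announced_carbs,
        time_sin=math.sin(angle),
        time_cos=math.cos(angle),
        iob=iob,
        cgm_now=float(hist[-1]),
    )


def gains_to_bolus(announced_carbs: float, cgm_now: float, iob: float,
                   gains: ActionGains, therapy: TherapyParams) -> float:
    """Dose implied by a gain vector; equals :func:`therapy.sbc_dose` at
    gains [1, 1, 1]. Clamped at zero."""
    if announced_carbs < 0:
        raise ValueError("announced_carbs must be >= 0")
    if not 40.0 <= cgm_now <= 400.0:
        raise ValueError("cgm_now must lie in the sensor range [40, 400]")
    dose = (gains.g_icr * announced_carbs / therapy.icr
            + gains.g_isf * therapy.correction_portion
            * (cgm_now - therapy.target_glucose) / therapy.isf
            - gains.g_iob * iob)
    return max(0.0, dose)


class DDPGAgent:
    """Actor, critic and their target networks, with update rules.

    The actor output head maps three linear pre-activations through
    ``g = mid + half * tanh(z)`` onto the gain range, so a zero
    pre-activation lands at the mid-range gain (1.1 for range [0.2, 2]),
    near the calculator-equivalent no-op. Exploration noise is added in gain
    space and re-clipped to the range.
    """

    def __init__(self, config: AgentConfig | None = None,
                 rng: np.random.Generator | None = None) -> None:
        self.config = config or AgentConfig()
        rng = rng if rng is not None else np.random.default_rng()
        c = self.config
        self.state_dim = c.history_length + 3 + 1  # history + carbs + (sin,cos) + iob
        self.action_dim = 3
        lo, hi = c.gain_range
        self._mid = 0.5 * (lo + hi)
        self._half = 0.5 * (hi - lo)

        self.actor = MLP((self.state_dim, *c.hidden, self.action_dim), rng)
        self.critic = MLP((self.state_dim + self.action_dim, *c.hidden, 1), rng)
        self.target_actor = self.actor.clone()
        self.target_critic = self.critic.clone()
        self.actor_opt = Adam(self.actor.params, lr=c.actor_lr)
        self.critic_opt = Adam(self.critic.params, lr=c.critic_lr,
                               weight_decay=c.critic_weight_decay)

    # -- state / action encodings ------------------------------------------

    def state_vector(self, s: AgentState) -> np.ndarray:
        """Fixed affine standardization of the raw observation."""
        c = self.config
        hist = (np.asarray(s.cgm_history) - c.cgm_center) / c.cgm_scale
        return np.concatenate([
            hist,
            [s.announced_carbs / c.carb_scale, s.time_sin, s.time_cos,
             s.iob / c.iob_scale],
        ])

    def states_matrix(self, states: list[AgentState]) -> np.ndarray:
        return np.stack([self.state_vector(s) for s in states])

    def _squash(self, z: np.ndarray) -> np.ndarray:
        return self._mid + self._half * np.tanh(z)

    def clip_gains(self, g: np.ndarray) -> np.ndarray:
        lo, hi = self.config.gain_range
        return np.clip(g, lo, hi)

    # -- acting -------------------------------------------------------------

    def act(self, state: AgentState, explore_noise_std: float = 0.0,
            rng: np.random.Generator | None = None) -> ActionGains:
        """Deterministic policy output, optionally perturbed by Gaussian
        noise in gain space, always clipped to the gain range."""
        z = self.actor.forward(self.state_vector(state))
        g = self._squash(z)[0]
        if explore_noise_std > 0:
            if rng is None:
                raise ValueError("exploration requires an rng")
            g = g + rng.normal(0.0, explore_noise_std, size=g.shape)
        g = self.clip_gains(g)
        return ActionGains(*[float(v) for v in g])

    # -- learning -----------------------------------------------------------

    def critic_update(self, batch: SampledBatch, gamma: float | None = None
                      ) -> tuple[float, np.ndarray]:
        """One importance-weighted TD regression step on the critic.

        Targets are ``y_i = r_i + gamma * Q'(s_{i+1}, mu'(s_{i+1}))``; the
        loss is the weighted mean squared TD error. Returns the loss and the
        per-sample TD errors (for replay-priority refresh).
        """
        gamma = self.config.gamma if gamma is None else gamma
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        trans = batch.transitions
        if not trans:
            raise ValueError("empty batch")
        s = self.states_matrix([t.state for t in trans])
        a = np.stack([t.action.as_array() for t in trans])
        r = np.array([t.reward for t in trans], dtype=float)
        s_next = self.states_matrix([t.next_state for t in trans])
        w = np.asarray(batch.importance_weights, dtype=float)
        if not (len(trans) == len(w) == len(r)):
            raise ValueError("batch shape mismatch")

        a_next = self._squash(self.target_actor.forward(s_next))
        q_next = self.target_critic.forward(
            np.concatenate([s_next, a_next], axis=1))[:, 0]
        y = r + gamma * q_next

        cache: list = []
        q = self.critic.forward(np.concatenate([s, a], axis=1), cache)[:, 0]
        td = y - q
        loss = float(np.mean(w * td ** 2))
        # dL/dq_i = -2 w_i td_i / B
        dout = (-2.0 * w * td / len(td))[:, None]
        grads, _ = self.critic.backward(cache, dout)
        self.critic_opt.step(grads)
        return loss, td

    def actor_update(self, batch: SampledBatch) -> float:
        """One deterministic-policy-gradient ascent step on the actor.

        Maximizes the batch-mean critic value of the actor's own action; the
        critic's weights are left untouched. Returns the pre-update mean Q.
        """
        trans = batch.transitions
        if not trans:
            raise ValueError("empty batch")
        s = self.states_matrix([t.state for t in trans])
        b = len(trans)

        actor_cache: list = []
        z = self.actor.forward(s, actor_cache)
        g = self._squash(z)

        critic_cache: list = []
        q = self.critic.forward(np.concatenate([s, g], axis=1), critic_cache)
        # minimize -mean(Q): gradient at critic output is -1/B
        dq = np.full((b, 1), -1.0 / b)
        _, dinput = self.critic.backward(critic_cache, dq)
        da = dinput[:, self.state_dim:]
        dz = da * self._half * (1.0 - np.tanh(z) ** 2)
        grads, _ = self.actor.backward(actor_cache, dz)
        self.actor_opt.step(grads)
        return float(np.mean(q))

    def soft_update(self, tau: float | None = None) -> None:
        """Blend online weights into the targets: theta' <- tau theta + (1-tau) theta'."""
        tau = self.config.tau if tau is None else tau
        if not 0.0 < tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        self.target_actor.blend_from(self.actor, tau)
        self.target_critic.blend_from(self.critic, tau)

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "config": asdict(self.config),
            "actor": self.actor.state_dict(),
            "critic": self.critic.state_dict(),
            "target_actor": self.target_actor.state_dict(),
            "target_critic": self.target_critic.state_dict(),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "DDPGAgent":
        cfg_dict = dict(state["config"])
        for key in ("hidden", "gain_range"):
            cfg_dict[key] = tuple(cfg_dict[key])
        agent = cls(AgentConfig(**cfg_dict), rng=np.random.default_rng(0))
        for name in ("actor", "critic", "target_actor", "target_critic"):
            net = MLP.from_state_dict(state[name])
            if net.sizes != getattr(agent, name).sizes:
                raise ValueError(f"checkpoint architecture mismatch for {name}")
            getattr(agent, name).copy_from(net)
        return agent
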