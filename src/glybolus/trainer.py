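"""Two-step training framework and evaluation.

Step one trains a population policy on the average virtual subject with
Gaussian exploration noise and no dose constraints, until the critic loss
converges. Step two initializes each subject's personalized policy from the
population weights (transfer learning) and fine-tunes it on that subject
with reduced exploration and the safety constraint active, for a short
subject-specific period. Evaluation freezes the policy (no learning, no
exploration) and reuses one scenario seed across compared policies so both
consume identical meals and sensor noise.

Each stored meal transition triggers a fixed number of gradient updates
(prioritized minibatch sampling, importance-weighted critic regression,
deterministic policy gradient, soft target blending), which amortizes the
scarcity of meal events (three per day) against network training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .agent import DDPGAgent
from .config import (
    AgentConfig,
    MealProtocol,
    ReplayConfig,
    SafetyConstraint,
    SimConfig,
    TrainConfig,
)
from .metrics import GlycemicReport, glycemic_report
from .patient import PatientParams
from .replay import ReplayMemory
from .scenario import generate_scenario
from .simulate import AgentPolicy, FixedGainsPolicy, SimulationLog, run_closed_loop
from .therapy import TherapyParams

__all__ = ["TrainResult", "train_population", "personalize", "evaluate",
           "train_agent"]


@dataclass
class TrainResult:
    """A trained agent plus its learning diagnostics."""

    agent: DDPGAgent
    learning_curve: list[dict] = field(default_factory=list)  # one row per update
    converged: bool = False
    n_updates: int = 0
    n_transitions: int = 0

    def checkpoint(self) -> dict:
        return self.agent.state_dict()


def _beta_schedule(cfg: ReplayConfig, update: int, total_updates: int) -> float:
    if not cfg.anneal_beta or total_updates <= 1:
        return cfg.beta_start
    frac = min(1.0, update / max(1, total_updates - 1))
    return cfg.beta_start + frac * (cfg.beta_end - cfg.beta_start)


def train_agent(agent: DDPGAgent, params: PatientParams,
                therapy: TherapyParams, config: TrainConfig,
                protocol: MealProtocol | None = None,
                replay_cfg: ReplayConfig | None = None,
                sim: SimConfig | None = None,
                constraint: SafetyConstraint | None = None) -> TrainResult:
    """Run the interactive training loop for one phase on one subject.

    The agent acts (with exploration noise) inside the closed loop; each
    completed meal transition is stored with max priority and followed by
    ``updates_per_transition`` prioritized minibatch updates. Training stops
    early when the moving average of the critic loss changes by less than
    the configured relative tolerance between consecutive windows.
    """
    replay_cfg = replay_cfg or ReplayConfig()
    memory = ReplayMemory(replay_cfg.capacity, replay_cfg.epsilon,
                          replay_cfg.alpha)
    ss = np.random.SeedSequence([int(config.rng_seed), 101])
    scen_seed, noise_seed, sample_seed, sim_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]
    scenario = generate_scenario(config.training_days, scen_seed, protocol)
    noise_rng = np.random.default_rng(noise_seed)
    sample_rng = np.random.default_rng(sample_seed)

    policy = AgentPolicy(agent, config.explore_noise_std, noise_rng)
    result = TrainResult(agent=agent)
    total_expected = (len(scenario.meals) * config.updates_per_transition) or 1
    window = config.convergence_window
    recent: list[float] = []
    prev_avg: float | None = None
    stop = False

    # replay warm-up before updates start; capped so short runs still train
    warmup = min(max(config.min_transitions, agent.config.batch_size),
                 max(1, len(scenario.meals) // 2))

    def on_transition(transition) -> None:
        nonlocal prev_avg, stop
        result.n_transitions += 1
        memory.add(transition)
        if stop or len(memory) < warmup:
            return
        for _ in range(config.updates_per_transition):
            beta = _beta_schedule(replay_cfg, result.n_updates, total_expected)
            batch = memory.sample(agent.config.batch_size, beta, sample_rng)
            loss, td = agent.critic_update(batch)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"critic loss diverged (loss={loss}) at update "
                    f"{result.n_updates}")
            memory.update_priorities(batch.indices, td)
            mean_q = float("nan")
            if (result.n_updates + 1) % config.actor_delay == 0:
                mean_q = agent.actor_update(batch)
            result.n_updates += 1
            if result.n_updates % agent.config.target_period == 0:
                agent.soft_update()
            result.learning_curve.append(dict(
                update=result.n_updates, critic_loss=loss, mean_q=mean_q,
                reward=transition.reward, beta=beta))
            recent.append(loss)
            if len(recent) >= 2 * window:
                avg = float(np.mean(recent[-window:]))
                prev = float(np.mean(recent[-2 * window:-window]))
                if prev != 0 and abs(avg - prev) / abs(prev) < config.convergence_rtol:
                    result.converged = True
                    stop = True
                    return

    run_closed_loop(params, therapy, scenario, policy, seed=sim_seed,
                    sim=sim, constraint=constraint,
                    on_transition=on_transition)
    return result


def train_population(params: PatientParams, therapy: TherapyParams,
                     config: TrainConfig | None = None,
                     agent_config: AgentConfig | None = None,
                     protocol: MealProtocol | None = None,
                     replay_cfg: ReplayConfig | None = None,
                     sim: SimConfig | None = None) -> TrainResult:
    """Step one: long-horizon exploratory training on the average subject,
    no safety constraints."""
    config = config or TrainConfig(phase="population")
    if config.phase != "population":
        raise ValueError("config.phase must be 'population'")
    agent = DDPGAgent(agent_config,
                      rng=np.random.default_rng(
                          np.random.SeedSequence([int(config.rng_seed), 7])))
    return train_agent(agent, params, therapy, config, protocol, replay_cfg,
                       sim, constraint=None)


def personalize(population_checkpoint: dict, params: PatientParams,
                therapy: TherapyParams, config: TrainConfig | None = None,
                constraint: SafetyConstraint | None = None,
                protocol: MealProtocol | None = None,
                replay_cfg: ReplayConfig | None = None,
                sim: SimConfig | None = None) -> TrainResult:
    """Step two: transfer-initialize from the population weights, fine-tune
    on one subject with the safety constraint enabled."""
    config = config or TrainConfig(phase="personalized", training_days=180,
                                   explore_noise_std=0.1)
    if config.phase != "personalized":
        raise ValueError("config.phase must be 'personalized'")
    agent = DDPGAgent.from_state_dict(population_checkpoint)
    constraint = constraint if constraint is not None else SafetyConstraint()
    if config.training_days == 0:
        return TrainResult(agent=agent)
    return train_agent(agent, params, therapy, config, protocol, replay_cfg,
                       sim, constraint=constraint)


def evaluate(policy_or_checkpoint, params: PatientParams,
             therapy: TherapyParams, days: int, seed: int,
             protocol: MealProtocol | None = None,
             sim: SimConfig | None = None,
             constraint: SafetyConstraint | None = None
             ) -> tuple[SimulationLog, GlycemicReport]:
    """Frozen-policy evaluation over ``days`` on the scenario drawn from
    ``seed``. Pass the same seed for each compared method: the meal sequence
    and sensor noise are then identical across methods.

    Accepts a policy callable, a DDPG agent, an agent checkpoint dict, or
    the string ``"sbc"`` for the calculator baseline.
    """
    if policy_or_checkpoint == "sbc":
        policy = FixedGainsPolicy()
    elif isinstance(policy_or_checkpoint, DDPGAgent):
        policy = AgentPolicy(policy_or_checkpoint, explore_noise_std=0.0)
    elif isinstance(policy_or_checkpoint, dict):
        policy = AgentPolicy(DDPGAgent.from_state_dict(policy_or_checkpoint),
                             explore_noise_std=0.0)
    elif callable(policy_or_checkpoint):
        policy = policy_or_checkpoint
    else:
        raise TypeError("unsupported policy specification")
    ss = np.random.SeedSequence([int(seed), 202])
    scen_seed, sim_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                           for s in ss.spawn(2)]
    scenario = generate_scenario(days, scen_seed, protocol)
    log = run_closed_loop(params, therapy, scenario, policy, seed=sim_seed,
                          sim=sim, constraint=constraint)
    return log, glycemic_report(log.cgm)
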