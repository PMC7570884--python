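"""Closed loop, safety constraint, two-step training and evaluation."""

import numpy as np
import pytest

from glybolus.agent import ActionGains, DDPGAgent
from glybolus.config import (
    AgentConfig,
    SafetyConstraint,
    TrainConfig,
)
from glybolus.reward import meal_reward
from glybolus.scenario import generate_scenario
from glybolus.simulate import (
    AgentPolicy,
    FixedGainsPolicy,
    apply_safety_constraint,
    run_closed_loop,
)
from glybolus.trainer import evaluate, personalize, train_population


class TestSafetyConstraint:
    def test_hyperglycemia_floors_dose_at_calculator(self):
        c = SafetyConstraint()
        assert apply_safety_constraint(4.0, 6.0, 250.0, c) == 6.0
        assert apply_safety_constraint(8.0, 6.0, 250.0, c) == 8.0

    def test_hypoglycemia_caps_dose_at_calculator(self):
        c = SafetyConstraint()
        assert apply_safety_constraint(8.0, 5.0, 60.0, c) == 5.0
        assert apply_safety_constraint(3.0, 5.0, 60.0, c) == 3.0

    def test_normoglycemia_passes_through(self):
        c = SafetyConstraint()
        assert apply_safety_constraint(4.0, 6.0, 120.0, c) == 4.0

    def test_disabled_constraint_is_identity(self):
        c = SafetyConstraint(enabled=False)
        assert apply_safety_constraint(4.0, 6.0, 250.0, c) == 4.0

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            SafetyConstraint(hyper_threshold=60.0, hypo_threshold=70.0)


class TestClosedLoop:
    def test_three_transitions_per_simulated_day(self, adult, adult_therapy):
        scenario = generate_scenario(4, rng_seed=3)
        log = run_closed_loop(adult, adult_therapy, scenario,
                              FixedGainsPolicy(), seed=0)
        assert len(log.transitions) == 3 * 4
        assert len(log.boluses) == 3 * 4

    def test_transition_reward_matches_recomputation_from_trace(
            self, adult, adult_therapy):
        scenario = generate_scenario(2, rng_seed=4)
        log = run_closed_loop(adult, adult_therapy, scenario,
                              FixedGainsPolicy(), seed=1)
        meals = scenario.meals
        for i, tr in enumerate(log.transitions):
            nxt = meals[i + 1].start_time if i + 1 < len(meals) else None
            assert tr.reward == pytest.approx(
                meal_reward(log.cgm, meals[i].start_time, nxt))

    def test_pinned_unit_gain_agent_reproduces_calculator_bitwise(
            self, adult, adult_therapy):
        scenario = generate_scenario(3, rng_seed=5)

        agent = DDPGAgent(AgentConfig(), np.random.default_rng(0))

        class PinnedPolicy(AgentPolicy):
            def __call__(self, state):
                return ActionGains(1.0, 1.0, 1.0)

        log_sbc = run_closed_loop(adult, adult_therapy, scenario,
                                  FixedGainsPolicy(), seed=9)
        log_pin = run_closed_loop(adult, adult_therapy, scenario,
                                  PinnedPolicy(agent), seed=9)
        assert np.array_equal(log_sbc.cgm.values, log_pin.cgm.values)
        assert np.array_equal(log_sbc.plasma, log_pin.plasma)
        assert [b.dose for b in log_sbc.boluses] == \
            [b.dose for b in log_pin.boluses]

    def test_executed_doses_equal_calculator_for_unit_gains(
            self, adult, adult_therapy):
        scenario = generate_scenario(2, rng_seed=6)
        log = run_closed_loop(adult, adult_therapy, scenario,
                              FixedGainsPolicy(), seed=2)
        for b in log.boluses:
            assert b.dose == pytest.approx(b.sbc_reference)

    def test_dataframe_log_schema(self, adult, adult_therapy):
        scenario = generate_scenario(1, rng_seed=7)
        log = run_closed_loop(adult, adult_therapy, scenario,
                              FixedGainsPolicy(), seed=3)
        df = log.to_dataframe()
        assert list(df.columns) == ["time_min", "cgm_mgdl", "plasma_mgdl",
                                    "bolus_IU", "basal_mU_min",
                                    "true_carbs_g", "announced_carbs_g"]
        assert df["bolus_IU"].sum() == pytest.approx(
            sum(b.dose for b in log.boluses))
        assert df["true_carbs_g"].sum() == pytest.approx(
            sum(m.true_carbs for m in log.meals))


def short_cfg(phase, days, seed, noise=0.3):
    return TrainConfig(phase=phase, training_days=days,
                       explore_noise_std=noise, rng_seed=seed,
                       updates_per_transition=2, min_transitions=6)


class TestTraining:
    def test_population_smoke_run_trains_and_reloads(self, adult,
                                                     adult_therapy):
        res = train_population(adult, adult_therapy,
                               short_cfg("population", 4, seed=1))
        assert res.n_transitions == 12
        assert res.n_updates > 0
        assert all(np.isfinite(row["critic_loss"])
                   for row in res.learning_curve)
        assert len(res.learning_curve) == res.n_updates
        reloaded = DDPGAgent.from_state_dict(res.checkpoint())
        for p, q in zip(reloaded.actor.params, res.agent.actor.params):
            assert np.array_equal(p, q)

    def test_training_is_seed_deterministic(self, adult, adult_therapy):
        a = train_population(adult, adult_therapy,
                             short_cfg("population", 4, seed=2))
        b = train_population(adult, adult_therapy,
                             short_cfg("population", 4, seed=2))
        for p, q in zip(a.agent.actor.params, b.agent.actor.params):
            assert np.array_equal(p, q)
        for p, q in zip(a.agent.critic.params, b.agent.critic.params):
            assert np.array_equal(p, q)

    def test_zero_personalization_days_returns_population_model(
            self, adult, adult_therapy):
        pop = train_population(adult, adult_therapy,
                               short_cfg("population", 3, seed=3))
        pers = personalize(pop.checkpoint(), adult, adult_therapy,
                           TrainConfig(phase="personalized", training_days=0))
        for p, q in zip(pers.agent.actor.params, pop.agent.actor.params):
            assert np.array_equal(p, q)

    def test_personalized_rollout_never_violates_the_constraint(
            self, adult, adult_therapy):
        constraint = SafetyConstraint()
        agent = DDPGAgent(AgentConfig(), np.random.default_rng(2))
        policy = AgentPolicy(agent, explore_noise_std=0.5,
                             rng=np.random.default_rng(3))
        scenario = generate_scenario(4, rng_seed=10)
        log = run_closed_loop(adult, adult_therapy, scenario, policy, seed=4,
                              constraint=constraint)
        assert len(log.boluses) == 12
        for b, s in zip(log.boluses, (t.state for t in log.transitions)):
            assert b.dose == apply_safety_constraint(
                b.proposed_dose, b.sbc_reference, s.cgm_now, constraint)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_diagnostic(self, adult, adult_therapy):
        cfg = short_cfg("population", 4, seed=6)
        ac = AgentConfig(critic_lr=1e6)  # guaranteed blow-up
        with pytest.raises(FloatingPointError, match="diverged"):
            train_population(adult, adult_therapy, cfg, agent_config=ac)


class TestEvaluation:
    def test_matched_seed_gives_identical_meal_sequences(self, adult,
                                                         adult_therapy):
        log_a, _ = evaluate("sbc", adult, adult_therapy, days=2, seed=42)
        agent = DDPGAgent(AgentConfig(), np.random.default_rng(0))
        log_b, _ = evaluate(agent, adult, adult_therapy, days=2, seed=42)
        assert log_a.meals == log_b.meals

    def test_report_partition_and_purity(self, adult, adult_therapy):
        _, rep1 = evaluate("sbc", adult, adult_therapy, days=2, seed=8)
        _, rep2 = evaluate("sbc", adult, adult_therapy, days=2, seed=8)
        assert rep1 == rep2
        assert rep1.tir + rep1.tbr + rep1.tar == pytest.approx(100.0,
                                                               abs=1e-9)

    def test_evaluation_does_not_mutate_the_checkpoint(self, adult,
                                                       adult_therapy):
        agent = DDPGAgent(AgentConfig(), np.random.default_rng(1))
        before = [p.copy() for p in agent.actor.params + agent.critic.params]
        evaluate(agent, adult, adult_therapy, days=1, seed=9)
        after = agent.actor.params + agent.critic.params
        for p, q in zip(after, before):
            assert np.array_equal(p, q)
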