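"""Shared test helpers: independent numerical oracles."""

import numpy as np

from glybolus.agent import ActionGains, AgentState, DDPGAgent
from glybolus.config import AgentConfig
from glybolus.replay import Transition


def critic_fd_max_rel_err(seed: int = 0, n: int = 4, gamma: float = 0.9,
                          eps: float = 1e-6) -> float:
    """Max relative error between the analytic critic-loss gradient and a
    central finite-difference estimate on a small random batch."""
    rng = np.random.default_rng(seed)
    ag = DDPGAgent(AgentConfig(hidden=(8, 8, 8), history_length=4,
                               critic_weight_decay=0.0), rng)

    def state():
        return AgentState(tuple(rng.uniform(60, 250, 4)),
                          float(rng.uniform(0, 150)),
                          float(rng.uniform(-1, 1)),
                          float(rng.uniform(-1, 1)),
                          float(rng.uniform(0, 8)), 150.0)

    trans = [Transition(state(), ActionGains(*rng.uniform(0.2, 2.0, 3)),
                        float(rng.uniform(-2, 0.5)), state())
             for _ in range(n)]
    w = rng.uniform(0.5, 1.0, n)

    s = ag.states_matrix([t.state for t in trans])
    a = np.stack([t.action.as_array() for t in trans])
    r = np.array([t.reward for t in trans])
    sn = ag.states_matrix([t.next_state for t in trans])

    def loss() -> float:
        an = ag._squash(ag.target_actor.forward(sn))
        qn = ag.target_critic.forward(np.concatenate([sn, an], axis=1))[:, 0]
        y = r + gamma * qn
        q = ag.critic.forward(np.concatenate([s, a], axis=1))[:, 0]
        return float(np.mean(w * (y - q) ** 2))

    an = ag._squash(ag.target_actor.forward(sn))
    qn = ag.target_critic.forward(np.concatenate([sn, an], axis=1))[:, 0]
    y = r + gamma * qn
    cache: list = []
    q = ag.critic.forward(np.concatenate([s, a], axis=1), cache)[:, 0]
    td = y - q
    grads, _ = ag.critic.backward(cache, (-2 * w * td / n)[:, None])

    max_rel = 0.0
    pick = np.random.default_rng(seed + 1)
    for p, g in zip(ag.critic.params, grads):
        for fi in pick.choice(p.size, size=min(5, p.size), replace=False):
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            if abs(fd) > 1e-9:
                max_rel = max(max_rel, abs(fd - g[idx]) / abs(fd))
    return max_rel
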