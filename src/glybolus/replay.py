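"""Prioritized experience replay (proportional variant).

Sampling probability of transition ``i`` is
``Pr(i) = (|d_i| + eps)^alpha / sum_n (|d_n| + eps)^alpha`` where ``d`` is
the TD error; ``alpha = 0`` recovers uniform sampling and ``eps > 0``
guarantees zero-error transitions remain sampleable. Importance weights
``w_i = (N Pr(i))^(-beta)`` are normalized by the maximum weight over the
memory so the largest possible weight is 1. Storage is a FIFO ring; lookup
is a linear scan (meal transitions are sparse, so the memory stays small).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["Transition", "SampledBatch", "ReplayMemory"]


@dataclass
class Transition:
    """One replay record <s_t, a_t, r_t, s_{t+1}> with its priority."""

    state: Any
    action: Any
    reward: float
    next_state: Any
    priority: float = 0.0
    time: float = 0.0   # simulator clock of the meal, for audit logs


@dataclass
class SampledBatch:
    transitions: list[Transition]
    indices: np.ndarray
    importance_weights: np.ndarray


class ReplayMemory:
    """FIFO replay memory with proportional prioritization."""

    def __init__(self, capacity: int, epsilon: float = 0.01,
                 alpha: float = 0.6) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.capacity = capacity
        self.epsilon = epsilon
        self.alpha = alpha
        self._items: list[Transition] = []
        self._next = 0  # ring-buffer write position once full

    def __len__(self) -> int:
        return len(self._items)

    @property
    def min_priority(self) -> float:
        """Priority floor: the priority a zero-TD-error transition gets."""
        return self.epsilon ** self.alpha

    def add(self, transition: Transition) -> None:
        """Store with max-priority insertion (floored at ``min_priority``)
        so every experience is trained on at least once."""
        p = max((t.priority for t in self._items), default=self.min_priority)
        transition.priority = max(p, self.min_priority)
        if len(self._items) < self.capacity:
            self._items.append(transition)
        else:
            self._items[self._next] = transition
            self._next = (self._next + 1) % self.capacity

    def probabilities(self) -> np.ndarray:
        p = np.array([t.priority for t in self._items], dtype=float)
        total = p.sum()
        if total <= 0:
            raise RuntimeError("all priorities zero; epsilon floor violated")
        return p / total

    def sample(self, batch_size: int, beta: float,
               rng: np.random.Generator) -> SampledBatch:
        """Draw ``batch_size`` transitions with replacement by priority."""
        if batch_size <= 0:
            raise ValueError("batch_size must be > 0")
        if not 0.0 <= beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not self._items:
            raise ValueError("cannot sample from an empty memory")
        pr = self.probabilities()
        n = len(self._items)
        idx = rng.choice(n, size=batch_size, replace=True, p=pr)
        weights = (n * pr[idx]) ** (-beta)
        weights /= np.max((n * pr) ** (-beta))
        return SampledBatch(
            transitions=[self._items[i] for i in idx],
            indices=idx,
            importance_weights=weights,
        )

    def update_priorities(self, indices: np.ndarray,
                          td_errors: np.ndarray) -> None:
        """Refresh priorities to ``(|delta| + eps)^alpha``."""
        td_errors = np.asarray(td_errors, dtype=float)
        for i, delta in zip(np.asarray(indices, dtype=int), td_errors):
            if not 0 <= i < len(self._items):
                raise IndexError(f"replay index {i} out of range")
            self._items[i].priority = (abs(float(delta))
                                       + self.epsilon) ** self.alpha

    def audit_rows(self) -> list[dict]:
        """Replay contents for the experiment log: time, reward, priority."""
        return [dict(time=t.time, reward=t.reward, priority=t.priority)
                for t in self._items]
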