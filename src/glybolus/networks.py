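"""Small fully connected networks with hand-written backpropagation.

The actor and critic are three-hidden-layer ReLU MLPs. Everything is plain
float64 numpy, which keeps seeded training bit-reproducible on one thread
and makes analytic gradients directly checkable against finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected network ``sizes[0] -> ... -> sizes[-1]``.

    Hidden activations are ReLU; the output is linear (heads such as the
    actor's bounded-gain squashing live in the caller). Weights use He
    initialization scaled for ReLU fan-in.
    """

    def __init__(self, sizes: tuple[int, ...],
                 rng: np.random.Generator | None = None) -> None:
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        rng = rng if rng is not None else np.random.default_rng()
        self.sizes = tuple(int(s) for s in sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        n_layers = len(self.sizes) - 1
        for i, (n_in, n_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            if i == n_layers - 1:
                # near-zero output layer: the initial policy/value surface is
                # flat, so learning starts from the mid-range action
                self.weights.append(rng.uniform(-3e-3, 3e-3, size=(n_in, n_out)))
            else:
                scale = np.sqrt(2.0 / n_in)
                self.weights.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        for w, new in zip(self.weights, params[:n]):
            w[...] = new
        for b, new in zip(self.biases, params[n:]):
            b[...] = new

    def copy_from(self, other: "MLP") -> None:
        self.set_params(other.params)

    def blend_from(self, other: "MLP", tau: float) -> None:
        """Soft update: self <- tau * other + (1 - tau) * self."""
        for p, q in zip(self.params, other.params):
            p *= (1.0 - tau)
            p += tau * q

    def clone(self) -> "MLP":
        out = MLP(self.sizes, rng=np.random.default_rng(0))
        out.copy_from(self)
        return out

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Batched forward pass; ``x`` is (B, sizes[0]).

        When ``cache`` (an empty list) is supplied, pre-activation records
        needed by :meth:`backward` are appended to it.
        """
        h = np.asarray(x, dtype=float)
        if h.ndim == 1:
            h = h[None, :]
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if cache is not None:
                cache.append(h)
            h = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
        if not np.all(np.isfinite(h)):
            raise FloatingPointError("non-finite network output")
        return h

    def backward(self, cache: list, dout: np.ndarray
                 ) -> tuple[list[np.ndarray], np.ndarray]:
        """Backpropagate ``dout`` (B, sizes[-1]) through a cached forward.

        Returns ``(grads, dx)`` where grads is ordered like :attr:`params`
        (weights then biases, input layer first) and dx is the gradient with
        respect to the network input.
        """
        grad_w = [np.zeros_like(w) for w in self.weights]
        grad_b = [np.zeros_like(b) for b in self.biases]
        delta = np.asarray(dout, dtype=float)
        if delta.ndim == 1:
            delta = delta[None, :]
        for i in range(len(self.weights) - 1, -1, -1):
            h_in = cache[i]
            if i < len(self.weights) - 1:
                # ReLU mask of this layer's output = next layer's cached input
                delta = delta * (cache[i + 1] > 0.0)
            grad_w[i] = h_in.T @ delta
            grad_b[i] = delta.sum(axis=0)
            delta = delta @ self.weights[i].T
        return grad_w + grad_b, delta

    def state_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLP":
        net = cls(tuple(state["sizes"]), rng=np.random.default_rng(0))
        net.set_params([np.array(w, dtype=float) for w in state["weights"]]
                       + [np.array(b, dtype=float) for b in state["biases"]])
        return net


class Adam:
    """Adam optimizer over a fixed list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay > 0.0:
                p -= self.lr * self.weight_decay * p  # decoupled L2 shrinkage
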