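"""Small fully-connected networks with explicit backpropagation.

NumPy implementations of the multilayer perceptrons, gradients and the
Adam optimizer used by the TD3 agent.  Sized for the low-dimensional
observation/action spaces of the infusion environment, where a handful
of 64-unit layers trains comfortably on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """ReLU MLP, optional tanh output.  Forward caches for backward()."""

    def __init__(self, sizes: list[int], tanh_out: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.sizes = list(sizes)
        self.tanh_out = tanh_out
        self.W = []
        self.b = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            lim = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
            self.W.append(rng.uniform(-lim, lim, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))
        self._cache = None

    # ------------------------------------------------------------- params
    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [p.copy() for p in params[:n]]
        self.b = [p.copy() for p in params[n:]]

    def copy(self) -> "MLP":
        out = MLP(self.sizes, tanh_out=self.tanh_out)
        out.set_parameters([p.copy() for p in self.parameters()])
        return out

    def polyak_from(self, other: "MLP", tau: float) -> None:
        for pt, ps in zip(self.parameters(), other.parameters()):
            pt *= 1.0 - tau
            pt += tau * ps

    # ------------------------------------------------------------ forward
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        acts = [x]
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(z, 0.0)
            elif self.tanh_out:
                h = np.tanh(z)
            else:
                h = z
            acts.append(h)
        self._cache = acts
        return h

    __call__ = forward

    # ----------------------------------------------------------- backward
    def backward(self, grad_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Backprop ``dL/d(output)`` through the cached forward pass.

        Returns (parameter gradients aligned with :meth:`parameters`,
        gradient with respect to the input).
        """
        if self._cache is None:
            raise RuntimeError("forward() must run before backward()")
        acts = self._cache
        g = np.atleast_2d(np.asarray(grad_out, dtype=np.float64))
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in reversed(range(len(self.W))):
            h_out = acts[i + 1]
            if i == len(self.W) - 1:
                gz = g * (1.0 - h_out**2) if self.tanh_out else g
            else:
                gz = g * (h_out > 0.0)
            gW[i] = acts[i].T @ gz
            gb[i] = gz.sum(axis=0)
            g = gz @ self.W[i].T
        return gW + gb, g


class Adam:
    """Adam optimizer over a list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
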