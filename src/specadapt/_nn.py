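"""Minimal fully-connected network machinery (forward, backprop, Adam).

The architectures used here are small stacks of dense layers, so the whole
engine fits in a few hundred lines of numpy.  Layers use He-scaled Gaussian
initialization for ReLU hidden units; output layers are linear (softmax is
applied by the loss).  All randomness flows through explicit
``numpy.random.Generator`` objects so training runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # numba fuses the Adam update into one memory pass; numpy works too
    from numba import njit

    @njit(cache=True)
    def _adam_kernel(p, g, m, v, b1, b2, alpha, eps_hat):  # pragma: no cover
        for i in range(p.size):
            mi = b1 * m[i] + (1.0 - b1) * g[i]
            vi = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            m[i] = mi
            v[i] = vi
            p[i] -= alpha * mi / (np.sqrt(vi) + eps_hat)

except ImportError:  # pragma: no cover
    _adam_kernel = None

__all__ = ["MLP", "Adam", "softmax", "softmax_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    Returns ``(loss, dloss/dlogits)`` with the gradient already averaged over
    the batch, ready to feed into :meth:`MLP.backward`.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = max(float(-np.log(p[np.arange(n), labels] + eps).mean()), 0.0)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return loss, grad


@dataclass
class MLP:
    """A dense feed-forward stack with ReLU hidden activations.

    ``dims = (d0, d1, ..., dk)`` gives k layers; the final layer is linear
    (no activation) so the same class serves as feature extractor, logistic
    head (single layer, softmax applied by the loss) and generator trunk.
    """

    dims: tuple[int, ...]
    params: list[np.ndarray] = field(default_factory=list)  # W1,b1,W2,b2,...

    @classmethod
    def init(cls, dims: tuple[int, ...], rng: np.random.Generator) -> "MLP":
        if any(d <= 0 for d in dims):
            raise ValueError(f"layer dimensions must be positive, got {dims}")
        params: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, scale, size=(fan_in, fan_out))
            params.append(w.astype(np.float32))
            params.append(np.zeros(fan_out, dtype=np.float32))
        return cls(tuple(dims), params)

    @property
    def n_layers(self) -> int:
        return len(self.dims) - 1

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[tuple]]:
        """Forward pass; returns output and a cache for :meth:`backward`.

        The cache holds, per layer, its input and the ReLU mask applied to
        its output (``None`` for the final, linear layer).
        """
        cache = []
        h = x
        for i in range(self.n_layers):
            x_in = h
            h = h @ self.params[2 * i] + self.params[2 * i + 1]
            mask = None
            if i < self.n_layers - 1:
                mask = h > 0.0
                h = h * mask
            cache.append((x_in, mask))
        return h, cache

    def backward(
        self, grad_out: np.ndarray, cache: list[tuple]
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backprop ``grad_out`` (dL/doutput) through the stack.

        Returns ``(grad_input, grads)`` where ``grads`` aligns with
        :attr:`params`.
        """
        grads: list[np.ndarray | None] = [None] * len(self.params)
        g = grad_out
        for i in range(self.n_layers - 1, -1, -1):
            x_in, mask = cache[i]
            if mask is not None:
                g = g * mask
            grads[2 * i] = x_in.T @ g
            grads[2 * i + 1] = g.sum(axis=0)
            g = g @ self.params[2 * i].T
        return g, grads  # type: ignore[return-value]

    # -- fast path used by permutation importance ---------------------------
    def first_preact(self, x: np.ndarray) -> np.ndarray:
        """Pre-activation of the first layer (``x @ W1 + b1``)."""
        return x @ self.params[0] + self.params[1]

    def forward_from_preact(self, z1: np.ndarray) -> np.ndarray:
        """Continue the forward pass from a first-layer pre-activation.

        Permuting one input column changes ``z1`` by a rank-one update; the
        caller exploits that to avoid recomputing the dominant matmul.
        """
        h = z1
        for i in range(1, self.n_layers):
            h = np.maximum(h, 0.0)
            h = h @ self.params[2 * i] + self.params[2 * i + 1]
        if self.n_layers == 1:
            return z1
        return h

    def copy(self) -> "MLP":
        return MLP(self.dims, [p.copy() for p in self.params])


class Adam:
    """Adam optimizer bound to one parameter list, updating in place."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._buf = [np.empty_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # fold both bias corrections into the step size (standard rewrite)
        alpha = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        eps_hat = self.eps * np.sqrt(1.0 - b2**self.t)
        if _adam_kernel is not None:
            for p, g, m, v in zip(self.params, grads, self.m, self.v):
                _adam_kernel(
                    p.ravel(),
                    np.ascontiguousarray(g, dtype=p.dtype).ravel(),
                    m.ravel(),
                    v.ravel(),
                    b1,
                    b2,
                    alpha,
                    eps_hat,
                )
            return
        for p, g, m, v, buf in zip(self.params, grads, self.m, self.v, self._buf):
            np.multiply(m, b1, out=m)
            np.multiply(g, 1.0 - b1, out=buf)
            np.add(m, buf, out=m)
            np.multiply(v, b2, out=v)
            np.multiply(g, g, out=buf)
            np.multiply(buf, 1.0 - b2, out=buf)
            np.add(v, buf, out=v)
            np.sqrt(v, out=buf)
            np.add(buf, eps_hat, out=buf)
            np.divide(m, buf, out=buf)
            np.multiply(buf, alpha, out=buf)
            np.subtract(p, buf, out=p)
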