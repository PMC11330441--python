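"""Minimal feed-forward training core: dense MLPs, Adam, and a WGAN-GP critic.

Everything here is plain numpy with hand-written reverse-mode gradients. The
critic deliberately has a single tanh hidden layer so that the gradient-penalty
term — whose parameter gradient needs derivatives *of* the input gradient — has a
closed form (derived below in :meth:`Critic.penalty_grads`) instead of requiring
a general double-backprop machine.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "linear":
        return z
    raise ValueError(name)


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return 1.0 - a * a
    if name == "relu":
        return (z > 0.0).astype(z.dtype)
    if name == "linear":
        return np.ones_like(z)
    raise ValueError(name)


class MLP:
    """Fully connected network with per-layer activations and manual backprop."""

    def __init__(self, sizes: list[int], activations: list[str], rng: np.random.Generator):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per layer")
        self.activations = list(activations)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (d_in + d_out))
            self.weights.append(rng.normal(0.0, scale, (d_in, d_out)))
            self.biases.append(np.zeros(d_out))

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        return out

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = x
        for w, b, act in zip(self.weights, self.biases, self.activations):
            z = a @ w + b
            out = _act(act, z)
            if cache is not None:
                cache.append((a, z, out))
            a = out
        return a

    def backward(self, dout: np.ndarray, cache: list) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of a scalar loss wrt params (same order as ``params``) and input."""
        grads: list[np.ndarray] = []
        d = dout
        for (a_in, z, a_out), w, act in zip(
            reversed(cache), reversed(self.weights), reversed(self.activations)
        ):
            dz = d * _act_grad(act, z, a_out)
            grads.append(dz.sum(axis=0))  # bias
            grads.append(a_in.T @ dz)  # weight
            d = dz @ w.T
        grads.reverse()
        return grads, d


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.5, beta2: float = 0.9):
        # beta defaults follow common WGAN-GP practice
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


class Critic:
    """One-hidden-layer tanh critic f(x) = w2 . tanh(W1 x + b1) + b2."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (d_in + d_hidden))
        self.W1 = rng.normal(0.0, scale, (d_hidden, d_in))
        self.b1 = np.zeros(d_hidden)
        self.w2 = rng.normal(0.0, np.sqrt(1.0 / d_hidden), d_hidden)
        self.b2 = 0.0

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.w2]

    def value(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x @ self.W1.T + self.b1) @ self.w2 + self.b2

    def input_grad(self, x: np.ndarray) -> np.ndarray:
        """d f / d x, one row per sample: W1^T (w2 * (1 - tanh^2))."""
        a = np.tanh(x @ self.W1.T + self.b1)
        s = self.w2 * (1.0 - a * a)
        return s @ self.W1

    def mean_value_grads(self, x: np.ndarray, sign: float) -> list[np.ndarray]:
        """Gradients of sign * mean_i f(x_i) wrt [W1, b1, w2]."""
        n = len(x)
        a = np.tanh(x @ self.W1.T + self.b1)
        s = (1.0 - a * a) * self.w2  # (n, m)
        c = sign / n
        dW1 = c * s.T @ x
        db1 = c * s.sum(axis=0)
        dw2 = c * a.sum(axis=0)
        return [dW1, db1, dw2]

    def penalty_grads(self, x_hat: np.ndarray) -> tuple[float, list[np.ndarray]]:
        """Value and parameter gradients of mean_i (||grad_x f(x_hat_i)|| - 1)^2.

        With a = tanh(W1 x + b1), s = w2 * (1 - a^2), the input gradient is
        g = W1^T s. Writing u = dP/dg = 2(||g|| - 1) g / ||g|| per sample, the
        chain rule through both the direct W1 dependence of g and the indirect
        dependence through a gives:

            dP/dw2_j   = (1 - a_j^2) (W1[j] . u)
            dP/db1_j   = -2 a_j (1 - a_j^2) w2_j (W1[j] . u)
            dP/dW1[jk] = u_k s_j - 2 a_j (1 - a_j^2) w2_j (W1[j] . u) x_k
        """
        n = len(x_hat)
        a = np.tanh(x_hat @ self.W1.T + self.b1)  # (n, m)
        one_m_a2 = 1.0 - a * a
        s = self.w2 * one_m_a2  # (n, m)
        g = s @ self.W1  # (n, d)
        norm = np.sqrt((g * g).sum(axis=1) + _EPS)  # (n,)
        penalty = float(((norm - 1.0) ** 2).mean())
        u = (2.0 * (norm - 1.0) / norm)[:, None] * g  # (n, d)
        w1u = u @ self.W1.T  # (n, m): W1[j] . u_i
        coeff = -2.0 * a * one_m_a2 * self.w2 * w1u  # (n, m)
        dw2 = (one_m_a2 * w1u).sum(axis=0) / n
        db1 = coeff.sum(axis=0) / n
        dW1 = (s.T @ u + coeff.T @ x_hat) / n
        return penalty, [dW1, db1, dw2]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
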