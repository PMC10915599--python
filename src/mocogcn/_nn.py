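"""Minimal dense neural-network primitives (NumPy).

The networks here are small (a few thousand parameters, full-batch
training on cohort-sized graphs), so forward/backward passes and the Adam
update rule are written directly against NumPy arrays. Everything is
deterministic given the RNG passed in.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_sum(probs: np.ndarray, y: np.ndarray) -> float:
    """Summed cross-entropy -sum_i log p_i[y_i] (natural log)."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p).sum())


def softmax_ce_grad(probs: np.ndarray, y: np.ndarray, idx: np.ndarray, n_rows: int) -> np.ndarray:
    """Gradient of summed CE w.r.t. logits; rows outside ``idx`` are zero.

    ``probs``/``y`` are already restricted to ``idx`` rows of the full
    logits matrix of ``n_rows`` rows.
    """
    g = np.zeros((n_rows, probs.shape[1]))
    d = probs.copy()
    d[np.arange(len(y)), y] -= 1.0
    g[idx] = d
    return g


def softmax_backprop(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Pull a gradient w.r.t. softmax outputs back to the logits, row-wise."""
    inner = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - inner)


class Adam:
    """Adam update rule over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
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
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
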