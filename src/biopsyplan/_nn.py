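"""Minimal NumPy building blocks for the policy and value networks.

Small tanh MLPs with hand-written backpropagation and an Adam optimizer.
The networks here are deliberately tiny: observations are pooled to a coarse
occupancy summary before entering the MLP, which keeps training tractable on
a single CPU while preserving the information the sampling task needs
(where the gland, lesion and recent needles sit relative to the grid).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "adaptive_pool"]


def adaptive_pool(volume: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    """Block-average a 3D array to ``out_shape`` (adaptive bin edges)."""
    a = np.asarray(volume, dtype=np.float32)
    for axis in range(3):
        n = a.shape[axis]
        bins = out_shape[axis]
        starts = (np.arange(bins) * n) // bins
        counts = np.diff(np.append(starts, n)).astype(np.float32)
        a = np.add.reduceat(a, starts, axis=axis)
        shape = [1, 1, 1]
        shape[axis] = bins
        a = a / counts.reshape(shape)
    return a


class MLP:
    """Fully connected tanh network with a linear output layer."""

    def __init__(
        self,
        sizes: tuple[int, ...],
        rng: np.random.Generator,
        zero_head: bool = False,
        head_scale: float = 1.0,
    ):
        self.sizes = tuple(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for k in range(len(sizes) - 1):
            fan_in, fan_out = sizes[k], sizes[k + 1]
            last = k == len(sizes) - 2
            if last and zero_head:
                w = np.zeros((fan_in, fan_out))
            else:
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                w = rng.uniform(-limit, limit, (fan_in, fan_out))
                if last:
                    w *= head_scale
            self.W.append(w)
            self.b.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """Returns (output, cache); ``x`` is (n, in_dim)."""
        h = np.asarray(x, dtype=float)
        cache = [h]
        for k in range(len(self.W) - 1):
            h = np.tanh(h @ self.W[k] + self.b[k])
            cache.append(h)
        out = h @ self.W[-1] + self.b[-1]
        return out, cache

    def backward(self, dout: np.ndarray, cache: list) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d loss / d output."""
        grads: dict[str, np.ndarray] = {}
        delta = np.asarray(dout, dtype=float)
        for k in range(len(self.W) - 1, -1, -1):
            h_in = cache[k]
            grads[f"W{k}"] = h_in.T @ delta
            grads[f"b{k}"] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.W[k].T) * (1.0 - cache[k] ** 2)
        return grads

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for k in range(len(self.W)):
            out[f"{prefix}W{k}"] = self.W[k]
            out[f"{prefix}b{k}"] = self.b[k]
        return out


class Adam:
    """Adam over a dict of named parameter arrays (updated in place)."""

    def __init__(self, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, g in grads.items():
            p = params[name]
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
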