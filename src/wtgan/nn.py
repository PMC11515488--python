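"""Minimal dense neural networks with manual backpropagation.

Just enough machinery for the adversarial models: fully connected
layers with he_uniform initialization, ReLU hidden activations, a
linear or sigmoid output, RMSprop and Adam optimizers, and hard weight
clipping (the Lipschitz constraint of the Wasserstein critic).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "RMSprop", "Adam", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)  # he_uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T


class MLP:
    """Dense network: ``sizes[0] -> ... -> sizes[-1]``.

    ReLU on every hidden layer; ``output`` is ``'linear'`` or
    ``'sigmoid'``.
    """

    def __init__(self, sizes: list[int], output: str = "linear", rng: np.random.Generator = None):
        if output not in ("linear", "sigmoid"):
            raise ValueError(f"unknown output activation {output!r}")
        if rng is None:
            rng = np.random.default_rng()
        self.output = output
        self.layers = [_Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self._pre: list[np.ndarray] = []
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = []
        h = x
        for i, layer in enumerate(self.layers):
            z = layer.forward(h)
            if i < len(self.layers) - 1:
                self._pre.append(z)
                h = np.maximum(z, 0.0)
            else:
                h = sigmoid(z) if self.output == "sigmoid" else z
        self._out = h
        return h

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backpropagate dLoss/d(output); returns dLoss/d(input).

        Parameter gradients are accumulated on the layers; combine with
        an optimizer step (or ignore them to use the net as a frozen
        conduit, e.g. the critic during a generator update).
        """
        g = grad_out
        if self.output == "sigmoid":
            g = g * self._out * (1.0 - self._out)
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                g = g * (self._pre[i] > 0.0)
            g = self.layers[i].backward(g)
        return g

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend([l.W, l.b])
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend([l.gW, l.gb])
        return out

    def clip_weights(self, c: float) -> None:
        for p in self.params:
            np.clip(p, -c, c, out=p)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class RMSprop:
    def __init__(self, net: MLP, lr: float = 5e-5, rho: float = 0.9, eps: float = 1e-8):
        self.net, self.lr, self.rho, self.eps = net, lr, rho, eps
        self.cache = [np.zeros_like(p) for p in net.params]

    def step(self) -> None:
        for p, g, c in zip(self.net.params, self.net.grads, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


class Adam:
    def __init__(self, net: MLP, lr: float = 2e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net, self.lr, self.beta1, self.beta2, self.eps = net, lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in net.params]
        self.v = [np.zeros_like(p) for p in net.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.net.params, self.net.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
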