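"""Minimal feed-forward building blocks with manual backpropagation.

Implements exactly what the spatiotemporal weighted regression needs — dense
layers, leaky rectifier, batch normalization, dropout — plus the Adadelta
optimizer and a multi-step learning-rate schedule.  Everything is float32,
seeded, and deterministic on a single platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adadelta", "MultiStepLR"]

_LEAK = 0.01


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, appropriate for the leaky rectifier
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class _LeakyReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, _LEAK * x)

    def backward(self, g):
        return np.where(self._mask, g, _LEAK * g)

    def params(self):
        return []


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=np.float32)
        self.beta = np.zeros(n, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=np.float32)
        self.running_var = np.ones(n, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        self._m = x.shape[0]
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        self.ggamma[...] = np.sum(g * self._xhat, axis=0)
        self.gbeta[...] = g.sum(axis=0)
        if not self._training:
            return g * self.gamma * self._istd
        m = self._m
        gx = g * self.gamma
        return (
            self._istd
            / m
            * (m * gx - gx.sum(axis=0) - self._xhat * np.sum(gx * self._xhat, axis=0))
        )

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class _Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


class MLP:
    """Dense network: hidden layers with optional batch-norm, leaky rectifier,
    and dropout; linear output layer."""

    def __init__(
        self,
        n_in: int,
        hidden: list[int],
        n_out: int,
        rng: np.random.Generator,
        *,
        dropout: float = 0.0,
        batchnorm: bool = False,
        out_init: float | None = None,
    ):
        self.layers = []
        prev = n_in
        for h in hidden:
            self.layers.append(_Linear(prev, h, rng))
            if batchnorm:
                self.layers.append(_BatchNorm(h))
            self.layers.append(_LeakyReLU())
            if dropout > 0:
                self.layers.append(_Dropout(dropout, rng))
            prev = h
        self.layers.append(_Linear(prev, n_out, rng))
        if out_init is not None:
            # start at a known output (e.g. all-ones weights = the global
            # stationary model); the zeroed weight matrix gains gradient from
            # its own update, so earlier layers unfreeze after one step
            last = self.layers[-1]
            last.W[...] = 0.0
            last.b[...] = out_init

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out.astype(np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p, _ in self.params()]
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for (p, _), s in zip(ps, state[: len(ps)]):
            p[...] = s
        extra = iter(state[len(ps) :])
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class Adadelta:
    """Adadelta with the PyTorch parameterization (lr scales the update)."""

    def __init__(self, params, lr: float = 1.0, rho: float = 0.9, eps: float = 1e-6):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.Eg = [np.zeros_like(p) for p, _ in params]
        self.Ed = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        for (p, g), Eg, Ed in zip(self.params, self.Eg, self.Ed):
            Eg *= self.rho
            Eg += (1 - self.rho) * g * g
            delta = np.sqrt(Ed + self.eps) / np.sqrt(Eg + self.eps) * g
            Ed *= self.rho
            Ed += (1 - self.rho) * delta * delta
            p -= self.lr * delta


class MultiStepLR:
    """Multiply the optimizer's lr by ``gamma`` when the epoch hits a milestone."""

    def __init__(self, optimizer: Adadelta, milestones: list[int], gamma: float = 0.8):
        self.optimizer = optimizer
        self.milestones = set(milestones)
        self.gamma = gamma
        self._epoch = 0

    def step(self) -> None:
        self._epoch += 1
        if self._epoch in self.milestones:
            self.optimizer.lr *= self.gamma
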