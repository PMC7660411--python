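"""Minimal fully-connected neural-network engine with manual backpropagation.

Provides exactly the building blocks the perturbation GAN needs: dense
layers, batch normalization, ReLU / leaky-ReLU / tanh activations, residual
blocks with identity skips, a sequential container, and an Adam optimizer.
All math is float64 NumPy; every layer caches its forward inputs so a
single ``backward`` pass accumulates parameter gradients and returns the
gradient with respect to the layer input (needed to push classifier and
discriminator gradients back into the generator).

Conventions
-----------
* Activations are row-major: ``x`` has shape ``(batch, features)``.
* ``backward`` ACCUMULATES into ``.grads`` (call ``zero_grad`` between
  optimizer steps) and may be called once per ``forward``.
* Batch-norm layers distinguish ``training`` (use batch statistics) from
  inference (use running statistics); ``update_stats=False`` lets a frozen
  network be evaluated with batch statistics without polluting its running
  averages (used when the generator's loss is backpropagated through the
  discriminator).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "BatchNorm",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "ResidualBlock",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class; stateless layers only implement forward/backward."""

    def forward(self, x: np.ndarray, training: bool = False,
                update_stats: bool | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    # flat state for checkpointing (includes non-trainable buffers)
    def state_arrays(self) -> list[np.ndarray]:
        return self.parameters()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(arrays) != len(own):
            raise ValueError(
                f"state mismatch: expected {len(own)} arrays, got {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


class Dense(Layer):
    """Affine layer ``y = x W + b``.

    ``init`` selects the fan-in scaling: ``"he"`` for ReLU-family
    activations, ``"glorot"`` for tanh/linear outputs.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he") -> None:
        if init == "he":
            scale = np.sqrt(2.0 / n_in)
        elif init == "glorot":
            scale = np.sqrt(2.0 / (n_in + n_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, training=False, update_stats=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class BatchNorm(Layer):
    """Batch normalization over the batch axis with learnable scale/shift.

    Running statistics use exponential averaging with the given momentum;
    they are consumed in inference mode so perturbation generation is
    deterministic for a frozen network.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x, training=False, update_stats=None):
        if update_stats is None:
            update_stats = training
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            if update_stats:
                self.running_mean = (self.momentum * self.running_mean
                                     + (1.0 - self.momentum) * mean)
                self.running_var = (self.momentum * self.running_var
                                    + (1.0 - self.momentum) * var)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        self._cache = (xhat, inv_sd, training, x.shape[0])
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, inv_sd, training, m = self._cache
        self.dgamma += (grad * xhat).sum(axis=0)
        self.dbeta += grad.sum(axis=0)
        gx = grad * self.gamma
        if not training:
            return gx * inv_sd
        # full batch-statistics gradient
        return (inv_sd / m) * (m * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]

    def state_arrays(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x, training=False, update_stats=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        self.alpha = alpha

    def forward(self, x, training=False, update_stats=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Tanh(Layer):
    def forward(self, x, training=False, update_stats=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class ResidualBlock(Layer):
    """Two dense+BN stages with an identity skip added before the final ReLU.

    Structure: ``out = ReLU(BN(Dense(ReLU(BN(Dense(x))))) + x)``; input and
    output widths are equal by construction.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 momentum: float = 0.9) -> None:
        self.d1 = Dense(dim, dim, rng, init="he")
        self.bn1 = BatchNorm(dim, momentum=momentum)
        self.act1 = ReLU()
        self.d2 = Dense(dim, dim, rng, init="he")
        self.bn2 = BatchNorm(dim, momentum=momentum)
        self.act_out = ReLU()
        self._inner = [self.d1, self.bn1, self.act1, self.d2, self.bn2]

    def forward(self, x, training=False, update_stats=None):
        h = x
        for layer in self._inner:
            h = layer.forward(h, training=training, update_stats=update_stats)
        return self.act_out.forward(h + x, training=training)

    def backward(self, grad):
        g = self.act_out.backward(grad)
        g_branch = g
        for layer in reversed(self._inner):
            g_branch = layer.backward(g_branch)
        return g_branch + g  # skip connection

    def parameters(self):
        return [p for l in self._inner for p in l.parameters()]

    def gradients(self):
        return [g for l in self._inner for g in l.gradients()]

    def state_arrays(self):
        return [a for l in self._inner for a in l.state_arrays()]

    def load_state_arrays(self, arrays):
        i = 0
        for l in self._inner:
            n = len(l.state_arrays())
            l.load_state_arrays(arrays[i:i + n])
            i += n


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, training=False, update_stats=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, update_stats=update_stats)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self):
        return [g for l in self.layers for g in l.gradients()]

    def state_arrays(self):
        return [a for l in self.layers for a in l.state_arrays()]

    def load_state_arrays(self, arrays):
        i = 0
        for l in self.layers:
            n = len(l.state_arrays())
            l.load_state_arrays(arrays[i:i + n])
            i += n


class Adam:
    """Adam optimizer over a network's parameter list."""

    def __init__(self, net: Layer, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.parameters()]
        self.v = [np.zeros_like(p) for p in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.net.parameters(), self.net.gradients(),
                              self.m, self.v):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        self.net.zero_grad()
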