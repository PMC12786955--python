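"""Feed-forward building blocks and the Adam optimizer.

Layers hold their weights as :class:`~condvae.autodiff.Tensor` leaves with
``requires_grad=True``. Initialization is fan-in uniform (LeCun-style) from a
caller-supplied ``numpy.random.Generator`` so that training is reproducible
from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "FTSwish", "MLP", "Adam", "flatten_t_swish"]


class Linear:
    """Affine map ``x @ W + b`` with fan-in uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(n_out,)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def flatten_t_swish(x: Tensor, threshold: float = -0.20) -> Tensor:
    """Flatten-T Swish activation: ``relu(x) * sigmoid(x) + T``.

    The negative part is flattened to the constant ``T`` (default −0.20, the
    value recommended by the activation's authors), which keeps a small
    negative mean and avoids dead units.
    """
    return x.relu() * x.sigmoid() + threshold


class FTSwish:
    def __init__(self, threshold: float = -0.20):
        self.threshold = threshold

    def __call__(self, x: Tensor) -> Tensor:
        return flatten_t_swish(x, self.threshold)


class MLP:
    """Single-hidden-layer perceptron: ``act(x W1 + b1) W2 + b2``.

    ``activation`` is any callable Tensor→Tensor; the output layer is linear
    (callers apply softmax/sigmoid heads themselves).
    """

    def __init__(self, n_in: int, n_hidden: int, n_out: int, activation,
                 rng: np.random.Generator):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.activation(self.fc1(x)))

    def hidden(self, x: Tensor) -> Tensor:
        return self.activation(self.fc1(x))

    @property
    def parameters(self) -> list[Tensor]:
        return self.fc1.parameters + self.fc2.parameters


class Adam:
    """Adam with optional per-step learning-rate override (for schedules)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
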