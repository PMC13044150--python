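"""Neural-network building blocks on top of the autodiff engine.

Parameters live in flat ``dict[str, Tensor]`` namespaces so a whole model is
one dictionary — trivial to serialize, seed, and hand to the optimizer.
Initialization is a symmetric uniform fan-in scheme drawn from a single
``numpy.random.Generator``, so a model is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, exp, relu, sqrt

Params = dict[str, Tensor]


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def linear_params(rng: np.random.Generator, d_in: int, d_out: int, prefix: str) -> Params:
    return {
        f"{prefix}.W": uniform_init(rng, (d_in, d_out), d_in),
        f"{prefix}.b": uniform_init(rng, (d_out,), d_in),
    }


def linear(x: Tensor, params: Params, prefix: str) -> Tensor:
    return x @ params[f"{prefix}.W"] + params[f"{prefix}.b"]


def layer_norm_params(d: int, prefix: str) -> Params:
    return {
        f"{prefix}.gamma": Tensor(np.ones(d), requires_grad=True),
        f"{prefix}.beta": Tensor(np.zeros(d), requires_grad=True),
    }


def layer_norm(x: Tensor, params: Params, prefix: str, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    normed = centered / sqrt(var + eps)
    return normed * params[f"{prefix}.gamma"] + params[f"{prefix}.beta"]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift for stability; the shift is a constant w.r.t. the gradient
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def mlp2(x: Tensor, params: Params, prefix: str, drop: float, rng) -> Tensor:
    """Linear -> ReLU -> dropout -> Linear."""
    h = dropout(relu(linear(x, params, f"{prefix}.fc1")), drop, rng)
    return linear(h, params, f"{prefix}.fc2")


class AdamW:
    """Decoupled-weight-decay Adam over a flat parameter dictionary."""

    def __init__(
        self,
        params: Params,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
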