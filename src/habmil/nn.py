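"""Neural-network building blocks and the Adam optimizer.

Layers own their parameters as :class:`~habmil.autodiff.Tensor` objects and
are initialized from an explicit ``numpy.random.Generator`` so that two
models built with the same seed have bit-identical parameters.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with recursive parameter discovery and train/eval state."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # checkpointing -------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        """Copies of all parameter arrays, in discovery order."""
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = a.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        self.weight = Tensor(
            _kaiming_uniform(rng, (in_dim, out_dim), in_dim, dtype), requires_grad=True
        )
        bound = 1.0 / math.sqrt(in_dim)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=(out_dim,)).astype(dtype),
            requires_grad=True,
        )

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    """Stride-1 'same' 3D convolution with an odd cubic kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        fan_in = in_ch * kernel**3
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in, dtype),
            requires_grad=True,
        )
        bound = 1.0 / math.sqrt(fan_in)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=(out_ch,)).astype(dtype), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class Dropout(Module):
    """Inverted dropout driven by a module-owned generator (seeded)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.rate, self.rng, self.training)


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay on gradients."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
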