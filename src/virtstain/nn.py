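"""Layers, parameter containers and the Adam optimizer.

Everything here is a thin, explicit wrapper over :mod:`virtstain.autodiff`.
Modules hold named ``Tensor`` parameters; ``state_dict``/``load_state_dict``
move raw arrays in and out for checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: children are discovered from instance attributes."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{full}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, v in own.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype).reshape(v.data.shape).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, std: float = 0.02, dtype=np.float32) -> Tensor:
    t = Tensor(rng.normal(0.0, std, size=shape).astype(dtype))
    t.requires_grad = True
    return t


def _zeros(shape, dtype=np.float32) -> Tensor:
    t = Tensor(np.zeros(shape, dtype=dtype))
    t.requires_grad = True
    return t


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, pad_mode: str = "zeros", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = _param(rng, (kernel, kernel, in_ch, out_ch))
        self.bias = _zeros((out_ch,))
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, pad_mode=self.pad_mode)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization with affine parameters."""

    eps = 1e-5

    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones((channels,), dtype=np.float32))
        self.gamma.requires_grad = True
        self.beta = _zeros((channels,))

    def forward(self, x):
        return ad.instance_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = _param(rng, (in_dim, out_dim), std=float(1.0 / np.sqrt(in_dim)))
        self.bias = _zeros((out_dim,))

    def forward(self, x):
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Adam:
    """Adam with per-parameter first/second moment state."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        out = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m.{i}"] = m.copy()
            out[f"v.{i}"] = v.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(state[f"m.{i}"]) for i in range(len(self.params))]
        self.v = [np.asarray(state[f"v.{i}"]) for i in range(len(self.params))]
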