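"""Layer abstractions over the autodiff core."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, param: Tensor):
        param.requires_grad = True
        param.name = name
        self._params[name] = param
        object.__setattr__(self, name, param)

    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix or "", self
        for name, m in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from m.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for mname, m in self._modules.items():
            sub = f"{prefix}.{mname}" if prefix else mname
            yield from m.named_parameters(sub)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, _BatchNorm):
                key = f"{name}." if name else ""
                out[f"{key}running_mean"] = m.running_mean.copy()
                out[f"{key}running_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.shape)
        for name, m in self.named_modules():
            if isinstance(m, _BatchNorm):
                key = f"{name}." if name else ""
                m.running_mean[...] = state[f"{key}running_mean"]
                m.running_var[...] = state[f"{key}running_var"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reset the weight-initialisation stream (deterministic model builds)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, groups=1, bias=True):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (cin // groups) * kernel * kernel
        self.register("weight", Tensor(_kaiming(
            _INIT_RNG, (cout, cin // groups, kernel, kernel), fan_in)))
        self.bias = None
        if bias:
            self.register("bias", Tensor(np.zeros(cout, dtype=np.float32)))

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), padding=(0, 0, 0), bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        kd, kh, kw = kernel
        fan_in = cin * kd * kh * kw
        self.register("weight", Tensor(_kaiming(_INIT_RNG, (cout, cin, kd, kh, kw), fan_in)))
        self.bias = None
        if bias:
            self.register("bias", Tensor(np.zeros(cout, dtype=np.float32)))

    def forward(self, x):
        return T.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class _BatchNorm(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.register("weight", Tensor(np.ones(channels, dtype=np.float32)))
        self.register("bias", Tensor(np.zeros(channels, dtype=np.float32)))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class BatchNorm2d(_BatchNorm):
    pass


class BatchNorm3d(_BatchNorm):
    pass


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
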