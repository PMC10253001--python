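"""Parameterised layers and the module/parameter registry."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autodiff import Tensor, conv2d, instance_norm


class Module:
    """Base class: registers parameters and submodules in insertion order."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((n, p.data.copy()) for n, p in self.named_parameters())

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def set_requires_grad(self, flag: bool, names=None) -> None:
        for n, p in self.named_parameters():
            if names is None or n in names:
                p.requires_grad = flag

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """Stride-1 same-padded 2D convolution with He-normal initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same padding")
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        w = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias)

    __call__ = forward


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation with learned affine parameters.

    Stateless (no running statistics), so teacher copies and EMA updates
    stay exact; stabilises training at the framework's learning rate.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = float(eps)
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32),
                           requires_grad=True)

    def forward(self, x):
        return instance_norm(x, self.gamma, self.beta, self.eps)

    __call__ = forward
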