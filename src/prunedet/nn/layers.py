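"""Neural-network layers on top of the autodiff core.

Mirrors the conventional Module API: parameters are float32 tensors with
``requires_grad=True``, ``state_dict`` round-trips through plain numpy arrays
(saved as ``.npz``), and every convolutional block follows the YOLO-family
convention of convolution + batch norm + SiLU unless stated otherwise.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np

from .autograd import Tensor, conv2d, max_pool2d, upsample_nearest2x


class Module:
    def __init__(self):
        self._training = True

    # -- traversal ---------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield (f"{prefix}.{name}" if prefix else name), v
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return sum(p.numel() for p in self.parameters())

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m._training = mode
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data for name, p in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{name}." if name else ""
                out[f"{key}running_mean"] = m.running_mean
                out[f"{key}running_var"] = m.running_var
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            arr = np.asarray(sd[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{name}." if name else ""
                m.running_mean = np.asarray(sd[f"{key}running_mean"], dtype=np.float32).copy()
                m.running_var = np.asarray(sd[f"{key}running_var"], dtype=np.float32).copy()

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)

    def forward(self, *args, **kw):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def append(self, m):
        self.mods.append(m)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: Optional[int] = None, groups: int = 1, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        kh, kw = (k, k) if isinstance(k, int) else (k[0], k[1])
        self.c_in, self.c_out, self.k = c_in, c_out, (kh, kw)
        self.stride = stride
        self.padding = (kh // 2, kw // 2) if padding is None else padding
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = c_in // groups * kh * kw
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (c_out, c_in // groups, kh, kw)),
                             requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, c_out), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(c), requires_grad=True)
        self.bias = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            inv = (var + self.eps) ** -0.5
            xn = xc * inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xn = (x - self.running_mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        return xn * self.weight.reshape(1, self.c, 1, 1) + self.bias.reshape(1, self.c, 1, 1)


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int = 1, padding: int = 0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x):
        return max_pool2d(x, self.k, self.stride, self.padding)


class Upsample2x(Module):
    def forward(self, x):
        return upsample_nearest2x(x)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(c_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (c_out, c_in)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, c_out), requires_grad=True) if bias else None

    def forward(self, x):
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y
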