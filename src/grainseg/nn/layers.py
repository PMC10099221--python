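"""Module system: containers, Conv2d/Linear/GroupNorm layers, initialization."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Sequential",
    "ModuleList",
    "ModuleDict",
    "Conv2d",
    "Linear",
    "GroupNorm",
    "ReLU",
    "Identity",
]

# Layer weights are drawn from this generator; detector construction reseeds
# it so that a model is reproducible from its config seed alone.
_rng = np.random.default_rng(0)


def seed(n: int) -> None:
    global _rng
    _rng = np.random.default_rng(int(n))


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._order = [str(i) for i in range(len(mods))]

    def forward(self, x):
        for k in self._order:
            x = self._modules[k](x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._order = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        k = str(len(self._order))
        setattr(self, k, m)
        self._order.append(k)
        return self

    def __iter__(self):
        return (self._modules[k] for k in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i: int):
        return self._modules[self._order[i]]


class ModuleDict(Module):
    def __init__(self, mods: dict[str, Module] | None = None):
        super().__init__()
        self._order = []
        for k, m in (mods or {}).items():
            self[k] = m

    def __setitem__(self, k: str, m: Module):
        setattr(self, k, m)
        if k not in self._order:
            self._order.append(k)

    def __getitem__(self, k: str):
        return self._modules[k]

    def keys(self):
        return list(self._order)

    def items(self):
        return [(k, self._modules[k]) for k in self._order]


class Conv2d(Module):
    """He-initialized 2-D convolution (NCHW)."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=True,
                 init_gain: float = 2.0):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = cin * kh * kw
        std = math.sqrt(init_gain / fan_in)
        self.weight = Parameter(_rng.normal(0.0, std, size=(cout, cin, kh, kw)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, init_gain: float = 2.0):
        super().__init__()
        std = math.sqrt(init_gain / cin)
        self.weight = Parameter(_rng.normal(0.0, std, size=(cin, cout)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GroupNorm(Module):
    """Batch-size-independent normalization; the tiny detector trains at
    batch 1-4 where batch statistics would be useless."""

    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % num_groups:
            raise ValueError("channels must be divisible by num_groups")
        self.groups, self.eps = num_groups, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x):
        N, C, H, W = x.shape
        g = self.groups
        v = x.reshape(N, g, (C // g) * H * W)
        mu = v.mean(axis=2, keepdims=True)
        centered = v - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        normed = normed.reshape(N, C, H, W)
        return normed * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x
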