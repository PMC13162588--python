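"""Layer abstractions over the autodiff core: parameter containers, 3D
convolution, batch normalization, linear layers and composition helpers."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module tree with training-mode flags and flat state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = {name: p for name, p in self.named_parameters()}
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()
        for name in bufs:
            parts = name.split(".")
            obj = self
            for part in parts[:-1]:
                if part.isdigit():
                    obj = obj[int(part)]
                else:
                    obj = getattr(obj, part)
            setattr(obj, parts[-1], np.asarray(state[name], dtype=np.float64).copy())


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_out, 1)), size=shape)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=(1, 1, 1), padding=(0, 0, 0), bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = F._triple(kernel_size)
        fan_out = out_channels * int(np.prod(k))
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, *k), fan_out))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = F._triple(stride)
        self.padding = F._triple(padding)

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_features, out_features), out_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class _BatchNorm(Module):
    """Normalization over all axes except the channel axis."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, channel_axis: int, ndim: int,
                 eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.channel_axis = channel_axis
        self.ndim = ndim
        shape = [1] * ndim
        shape[channel_axis] = num_features
        self.weight = Parameter(np.ones(shape))
        self.bias = Parameter(np.zeros(shape))
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(self.ndim) if i != self.channel_axis)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mean) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return xhat * self.weight + self.bias


class BatchNorm3d(_BatchNorm):
    def __init__(self, num_features: int, **kw):
        super().__init__(num_features, channel_axis=1, ndim=5, **kw)


class BatchNorm1d(_BatchNorm):
    def __init__(self, num_features: int, **kw):
        super().__init__(num_features, channel_axis=1, ndim=2, **kw)


class GroupNorm3d(Module):
    """Per-sample normalization over channel groups of [B, C, T, H, W].

    Batch-size independent: train and eval behave identically, and no
    information can leak between the samples of a batch — the preferred
    normalization when batches are tiny."""

    def __init__(self, num_features: int, num_groups: int = 8,
                 eps: float = 1e-5):
        super().__init__()
        while num_features % num_groups:
            num_groups -= 1
        self.num_groups = max(num_groups, 1)
        self.eps = eps
        self.weight = Parameter(np.ones((1, num_features, 1, 1, 1)))
        self.bias = Parameter(np.zeros((1, num_features, 1, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        b, c, t, h, w = x.shape
        g = self.num_groups
        xg = x.reshape(b, g, c // g, t, h, w)
        mean = xg.mean(axis=(2, 3, 4, 5), keepdims=True)
        var = ((xg - mean) ** 2).mean(axis=(2, 3, 4, 5), keepdims=True)
        xhat = ((xg - mean) / (var + self.eps).sqrt()).reshape(b, c, t, h, w)
        return xhat * self.weight + self.bias


class LayerNorm1d(Module):
    """Per-row normalization of [N, F] features (batch-size independent)."""

    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones((1, num_features)))
        self.bias = Parameter(np.zeros((1, num_features)))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=1, keepdims=True)
        return (x - mean) / (var + self.eps).sqrt() * self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Dropout(Module):
    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = float(p)
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class SGD:
    """Stochastic gradient descent with classical momentum and decoupled-style
    L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def state_dict(self):
        return {"velocity": [v.copy() for v in self.velocity]}

    def load_state_dict(self, state):
        self.velocity = [np.asarray(v).copy() for v in state["velocity"]]
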