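"""Neural-network modules built on the :mod:`raftseg.nn.tensor` engine.

The surface intentionally mirrors the conventions of mainstream deep
learning frameworks (``Module``, ``Conv2d``, ``BatchNorm2d``...) so the
architecture code reads like any other segmentation network.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor, conv2d, max_pool2d, upsample_bilinear2x

__all__ = [
    "Module", "Parameter", "Conv2d", "BatchNorm2d", "ReLU", "GELU",
    "Sigmoid", "MaxPool2d", "UpsampleBilinear2x", "Sequential", "Identity",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module base: child/parameter registration, train/eval mode,
    flat state dicts keyed by dotted paths."""

    def __init__(self):
        self._params: OrderedDict[str, Parameter] = OrderedDict()
        self._buffers: OrderedDict[str, np.ndarray] = OrderedDict()
        self._children: OrderedDict[str, Module] = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for cn, child in self._children.items():
            yield from child.named_parameters(prefix + cn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ---------------------------------------------
    def state_dict(self, prefix: str = "") -> OrderedDict:
        out = OrderedDict()
        for n, p in self._params.items():
            out[prefix + n] = p.data.copy()
        for n, b in self._buffers.items():
            out[prefix + n] = np.array(b, copy=True)
        for cn, child in self._children.items():
            out.update(child.state_dict(prefix + cn + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for n, p in self._params.items():
            key = prefix + n
            if p.data.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}: {p.data.shape} vs {state[key].shape}")
            p.data = state[key].astype(p.data.dtype).copy()
        for n in list(self._buffers):
            key = prefix + n
            self._buffers[n] = np.array(state[key], copy=True)
            object.__setattr__(self, n, self._buffers[n])
        for cn, child in self._children.items():
            child.load_state_dict(state, prefix + cn + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride: int = 1, padding=0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        if in_channels % groups:
            raise ValueError(f"in_channels {in_channels} not divisible by groups {groups}")
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kh * kw
        self.stride, self.padding, self.groups = stride, padding, groups
        self.weight = Parameter(he_uniform(rng, (out_channels, in_channels // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel; running stats in eval."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= (1 - m)
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= (1 - m)
            self._buffers["running_var"] += m * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return upsample_bilinear2x(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._order = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._order.append(m)

    def forward(self, x):
        for m in self._order:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._order)
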