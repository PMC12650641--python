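"""Neural-network layers on top of the autograd engine.

Mirrors the familiar layer vocabulary (Linear, Conv2d, BatchNorm, LayerNorm,
Dropout, multi-head self-attention) with explicit seeded initialisation:
every module takes a ``numpy.random.Generator`` so a model build is fully
reproducible from one integer seed.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np

from .autograd import Tensor, no_grad
from . import functional as F

__all__ = [
    "Module", "Parameter", "Sequential", "Linear", "Conv2d", "DepthwiseConv1d",
    "BatchNorm1d", "BatchNorm2d", "LayerNorm", "Dropout", "GELU", "ReLU",
    "Sigmoid", "MultiheadSelfAttention", "Identity",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self._parameters: "OrderedDict[str, Parameter]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ------------------------------------------------------------

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        state = OrderedDict()
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, b in self.named_buffers():
            state[name] = np.asarray(b).copy()
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = self._buffer_owners()
        missing = set(own) | set(bufs)
        for name, value in state.items():
            value = np.asarray(value)
            if name in own:
                if own[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = value.astype(own[name].data.dtype).copy()
            elif name in bufs:
                owner, attr = bufs[name]
                owner.register_buffer(attr, value.copy())
            else:
                raise KeyError(f"unexpected key in state dict: {name}")
            missing.discard(name)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)}")

    def _buffer_owners(self, prefix: str = ""):
        out = {}
        for name in self._buffers:
            out[prefix + name] = (self, name)
        for mname, m in self._modules.items():
            out.update(m._buffer_owners(prefix + mname + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_trainable_parameters(model: Module) -> int:
    """Total number of scalar entries across trainable tensors."""
    return int(sum(p.data.size for p in model.parameters() if p.requires_grad))


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features),
                                                 in_features))
        self.bias = Parameter(_kaiming_uniform(rng, (out_features,), in_features)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0, bias: bool = True):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        self.in_channels, self.padding = in_channels, padding
        self.weight = Parameter(
            _kaiming_uniform(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(_kaiming_uniform(rng, (out_channels,), fan_in)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.padding)


class DepthwiseConv1d(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        self.padding = padding
        self.weight = Parameter(
            _kaiming_uniform(rng, (channels, kernel_size), kernel_size))
        self.bias = Parameter(_kaiming_uniform(rng, (channels,), kernel_size)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv1d(x, self.weight, self.bias, self.padding)


class _BatchNorm(Module):
    """Normalise over all axes except the channel axis; tracks running stats."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    _channel_axis = 1

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != self._channel_axis)
        bshape = [1] * x.ndim
        bshape[self._channel_axis] = -1
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=axes, keepdims=True)
            with no_grad():
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean
                                     + m * mean.data.reshape(-1))
                self.running_var = ((1 - m) * self.running_var
                                    + m * var.data.reshape(-1))
                self._buffers["running_mean"] = self.running_mean
                self._buffers["running_var"] = self.running_var
            xhat = centred * (var + self.eps) ** -0.5
        else:
            mean = Tensor(self.running_mean.reshape(bshape))
            var = Tensor(self.running_var.reshape(bshape))
            xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.weight.reshape(bshape) + self.bias.reshape(bshape)


class BatchNorm1d(_BatchNorm):
    pass


class BatchNorm2d(_BatchNorm):
    pass


class LayerNorm(Module):
    """Normalise over the trailing dimension (pre-affine zero mean, unit var)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centred = x - mean
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred * (var + self.eps) ** -0.5 * self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from a module-owned
    generator so training runs are reproducible from the build seed."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype.type) / keep
        return x * Tensor(mask)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MultiheadSelfAttention(Module):
    """Standard multi-head scaled-dot self-attention over (B, T, D).

    Projections carry no bias (the surrounding pre-norm residual blocks make
    additive offsets redundant).  The most recent attention weights are kept
    on ``last_attention`` (detached, shape (B, heads, T, T)) for inspection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dropout_p: float = 0.1):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng, bias=False)
        self.k_proj = Linear(d_model, d_model, rng, bias=False)
        self.v_proj = Linear(d_model, d_model, rng, bias=False)
        self.out_proj = Linear(d_model, d_model, rng, bias=False)
        self.dropout = Dropout(dropout_p, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        q = self._split(self.q_proj(x))
        k = self._split(self.k_proj(x))
        v = self._split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data.copy()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.dropout(self.out_proj(out))
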