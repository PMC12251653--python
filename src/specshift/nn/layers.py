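"""Neural-network building blocks on the autodiff core.

Initialisation is He-uniform (fan-in scaled) from a caller-supplied numpy
Generator, so a model built twice from the same seed has bit-identical
parameters.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, adaptive_avg_pool1d, conv1d, depthwise_conv1d

__all__ = [
    "Module", "Conv1d", "DepthwiseConv1d", "PointwiseConv1d", "Linear",
    "SEBlock", "Dropout", "AdaptiveAvgPool1d", "AvgPool1d",
]


class Module:
    """Minimal container: children are discovered from instance attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Tensor):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}[{i}]")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_uniform(rng: np.random.Generator, shape, fan_in: int,
                dtype=np.float64) -> np.ndarray:
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, shape).astype(dtype)


class Conv1d(Module):
    """Standard 1-D convolution with 'same' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, bias: bool = True,
                 dtype=np.float64):
        fan_in = in_channels * kernel_size
        self.stride = stride
        self.weight = Tensor(
            _he_uniform(rng, (out_channels, in_channels, kernel_size), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = Tensor(_he_uniform(rng, out_channels, fan_in, dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride)


class DepthwiseConv1d(Module):
    """Per-channel (depthwise) 1-D convolution with 'same' padding."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = True, dtype=np.float64):
        self.stride = stride
        self.weight = Tensor(_he_uniform(rng, (channels, kernel_size), kernel_size, dtype),
                             requires_grad=True)
        self.bias = Tensor(_he_uniform(rng, channels, kernel_size, dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv1d(x, self.weight, self.bias, stride=self.stride)


class PointwiseConv1d(Conv1d):
    """1x1 convolution (channel mixing)."""

    def __init__(self, in_channels: int, out_channels: int, rng, bias: bool = True,
                 dtype=np.float64):
        super().__init__(in_channels, out_channels, 1, rng, stride=1, bias=bias,
                         dtype=dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        self.weight = Tensor(_he_uniform(rng, (in_features, out_features), in_features, dtype),
                             requires_grad=True)
        self.bias = Tensor(_he_uniform(rng, out_features, in_features, dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Global average pooling over the length axis, a bottleneck pair of fully
    connected layers (ReLU then sigmoid), and channelwise rescaling of the
    input.  The most recent gate values are kept on ``last_gates`` for
    inspection.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4,
                 dtype=np.float64):
        hidden = max(1, channels // reduction)
        self.fc_reduce = Linear(channels, hidden, rng, dtype=dtype)
        self.fc_expand = Linear(hidden, channels, rng, dtype=dtype)
        self.last_gates: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        z = x.mean(axis=2)  # squeeze: (N, C)
        g = self.fc_expand(self.fc_reduce(z).relu()).sigmoid()
        self.last_gates = g.data.copy()
        n, c = g.data.shape
        return x * g.reshape(n, c, 1)


class Dropout(Module):
    """Inverted dropout; a no-op at p=0 or in eval mode (draws no randoms)."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if not training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype))


class AdaptiveAvgPool1d(Module):
    """Average pooling to a fixed output length.

    The length axis is partitioned into ``out_len`` contiguous bins of
    near-equal size (``[floor(i*L/P), floor((i+1)*L/P))``) and each bin is
    averaged.
    """

    def __init__(self, out_len: int, dtype=np.float64):
        if out_len < 1:
            raise ValueError("out_len must be >= 1")
        self.out_len = out_len
        self.dtype = dtype

    def forward(self, x: Tensor) -> Tensor:
        return adaptive_avg_pool1d(x, self.out_len)


class AvgPool1d(Module):
    """Fixed-stride average pooling (used on residual paths when a block
    downsamples)."""

    def __init__(self, stride: int, dtype=np.float64):
        self.stride = stride
        self.dtype = dtype

    def forward(self, x: Tensor) -> Tensor:
        s = self.stride
        if s == 1:
            return x
        N, C, L = x.data.shape
        L_out = (L + s - 1) // s  # matches 'same'-padded strided conv length
        if L % s == 0:
            return x.reshape(N, C, L_out, s).mean(axis=3)
        return adaptive_avg_pool1d(x, L_out)
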