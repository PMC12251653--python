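"""Multi-scale 1-D convolutional regression network for NIR spectra.

The reference architecture: a standard convolutional stem, a stack of
RX-Inception blocks — four parallel depthwise-separable branches with
different kernel sizes, channel concatenation, pointwise fusion,
squeeze-and-excitation recalibration and a residual connection — followed by
adaptive average pooling, dropout, and a two-layer fully connected head that
exposes both a 100-wide feature vector and the scalar prediction.

Parameters are organised into four named groups (``stem``, ``blocks``,
``fc1``, ``fc2``), the unit of layer freezing during calibration transfer.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np

from .nn import (
    AdaptiveAvgPool1d,
    AvgPool1d,
    Conv1d,
    DepthwiseConv1d,
    Dropout,
    Linear,
    Module,
    PointwiseConv1d,
    SEBlock,
    Tensor,
    concat,
)

__all__ = [
    "ModelConfig",
    "NetworkHandle",
    "RXInceptionBlock",
    "build_model",
    "forward",
    "count_parameters",
    "dsc_param_count",
    "standard_conv_param_count",
    "corn_config",
    "tablet_config",
    "GROUPS",
]

GROUPS = ("stem", "blocks", "fc1", "fc2")
FEATURE_WIDTH = 100  # width of the first fully connected layer's output


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``kernel_sizes`` are the four branch kernels M1–M4 of every RX-Inception
    block; ``pool_len`` is the adaptive-pool output length, so the first
    fully connected layer has ``block_channels[-1] * pool_len`` inputs.
    """

    kernel_sizes: tuple[int, int, int, int] = (3, 5, 13, 3)
    in_channels: int = 1
    stem_channels: int = 16
    stem_kernel: int = 7
    block_channels: tuple[int, ...] = (32, 64, 100)
    pool_len: int = 256
    dropout_p: float = 0.0
    se_reduction: int = 4
    downsample_first: bool = True
    dtype: str = "float32"  # parameter precision; float32 trains ~2x faster
    fc1_in: int | None = None  # derived when None; validated when given

    def __post_init__(self) -> None:
        for k in tuple(self.kernel_sizes) + (self.stem_kernel,):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
        if len(self.kernel_sizes) != 4:
            raise ValueError("exactly four branch kernel sizes are required")
        for c in self.block_channels:
            if c % 4 != 0:
                raise ValueError(
                    f"block channel counts must be divisible by the 4 branches, got {c}"
                )
        if self.pool_len < 1:
            raise ValueError("pool_len must be >= 1")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        expected = self.block_channels[-1] * self.pool_len
        if self.fc1_in is None:
            self.fc1_in = expected
        elif self.fc1_in != expected:
            raise ValueError(
                f"fc1 input width {self.fc1_in} inconsistent with "
                f"block_channels[-1]*pool_len = {expected}"
            )

    @property
    def fc1_dims(self) -> tuple[int, int]:
        return (self.fc1_in, FEATURE_WIDTH)

    @property
    def fc2_dims(self) -> tuple[int, int]:
        return (FEATURE_WIDTH, 1)

    def to_dict(self) -> dict:
        return {
            "kernel_sizes": list(self.kernel_sizes),
            "in_channels": self.in_channels,
            "stem_channels": self.stem_channels,
            "stem_kernel": self.stem_kernel,
            "block_channels": list(self.block_channels),
            "pool_len": self.pool_len,
            "dropout_p": self.dropout_p,
            "se_reduction": self.se_reduction,
            "downsample_first": self.downsample_first,
            "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["kernel_sizes"] = tuple(d["kernel_sizes"])
        d["block_channels"] = tuple(d["block_channels"])
        return cls(**d)


def corn_config(**overrides) -> ModelConfig:
    """Configuration for 700-point grain spectra (branch kernels 3/5/13/3,
    no dropout, 25 600-wide flattened features)."""
    base = dict(kernel_sizes=(3, 5, 13, 3), pool_len=256, dropout_p=0.0)
    base.update(overrides)
    return ModelConfig(**base)


def tablet_config(**overrides) -> ModelConfig:
    """Configuration for 650/530-point pharmaceutical spectra (branch kernels
    5/9/15/3, dropout 0.5, 2 500-wide flattened features)."""
    base = dict(kernel_sizes=(5, 9, 15, 3), pool_len=25, dropout_p=0.5)
    base.update(overrides)
    return ModelConfig(**base)


# ----------------------------------------------------------------------
# Blocks
# ----------------------------------------------------------------------

class RXInceptionBlock(Module):
    """Four depthwise-separable branches + fusion + SE + residual.

    All branches share the block stride so their outputs concatenate; a
    strided block average-pools the residual path to match.  The residual
    shortcut uses a pointwise projection whenever channel counts differ.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_sizes: tuple[int, int, int, int],
                 rng: np.random.Generator, stride: int = 1, se_reduction: int = 4,
                 dtype=np.float64):
        branch_c = out_channels // 4
        self.branches = []
        for k in kernel_sizes:
            self.branches.append(DepthwiseConv1d(in_channels, k, rng, stride=stride,
                                                 dtype=dtype))
            self.branches.append(PointwiseConv1d(in_channels, branch_c, rng, dtype=dtype))
        self.fuse = PointwiseConv1d(out_channels, out_channels, rng, dtype=dtype)
        self.se = SEBlock(out_channels, rng, reduction=se_reduction, dtype=dtype)
        self.pool = AvgPool1d(stride, dtype=dtype)
        self.project = (
            PointwiseConv1d(in_channels, out_channels, rng, bias=False, dtype=dtype)
            if in_channels != out_channels else None
        )

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        for i in range(0, len(self.branches), 2):
            dw, pw = self.branches[i], self.branches[i + 1]
            outs.append(pw(dw(x)).relu())
        y = self.se(self.fuse(concat(outs, axis=1)))
        shortcut = self.pool(x)
        if self.project is not None:
            shortcut = self.project(shortcut)
        return (y + shortcut).relu()


class PlainConvBlock(Module):
    """Ablation block: one standard convolution in place of RX-Inception
    (no multi-branch, no SE, no residual)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, dtype=np.float64):
        self.conv = Conv1d(in_channels, out_channels, kernel_size, rng, stride=stride,
                           dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()


# ----------------------------------------------------------------------
# Network handle
# ----------------------------------------------------------------------

class NetworkHandle(Module):
    """A built network plus its config, target scaler and parameter groups."""

    def __init__(self, config: ModelConfig, seed: int, block_factory: str = "rx"):
        self.config = config
        self.seed = seed
        self.block_factory = block_factory
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype).type
        self.stem = Conv1d(config.in_channels, config.stem_channels,
                           config.stem_kernel, rng, dtype=dtype)
        self.blocks = []
        in_c = config.stem_channels
        for bi, out_c in enumerate(config.block_channels):
            stride = 2 if (bi == 0 and config.downsample_first) else 1
            if block_factory == "rx":
                blk = RXInceptionBlock(in_c, out_c, config.kernel_sizes, rng,
                                       stride=stride, se_reduction=config.se_reduction,
                                       dtype=dtype)
            elif block_factory == "plain":
                blk = PlainConvBlock(in_c, out_c, config.kernel_sizes[0], rng,
                                     stride=stride, dtype=dtype)
            else:
                raise ValueError(f"unknown block factory {block_factory!r}")
            self.blocks.append(blk)
            in_c = out_c
        self.pool = AdaptiveAvgPool1d(config.pool_len, dtype=dtype)
        self.dropout = Dropout(config.dropout_p, np.random.default_rng([seed, 1]))
        self.fc1 = Linear(*config.fc1_dims, rng, dtype=dtype)
        self.fc2 = Linear(*config.fc2_dims, rng, dtype=dtype)
        # input/target standardisation learned during pre-training
        self.x_mean: np.ndarray | None = None  # mean master spectrum
        self.x_scale = 1.0                     # global absorbance scale
        self.y_mean = 0.0
        self.y_sd = 1.0

    # -- parameter groups ----------------------------------------------
    def group_parameters(self, groups=GROUPS) -> list[Tensor]:
        """Parameters in the union of the named groups (stable order)."""
        unknown = set(groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown parameter group(s) {sorted(unknown)}")
        out: list[Tensor] = []
        for g in GROUPS:  # canonical order, independent of request order
            if g not in groups:
                continue
            mod = {"stem": self.stem, "fc1": self.fc1, "fc2": self.fc2}.get(g)
            if g == "blocks":
                for b in self.blocks:
                    out.extend(b.parameters())
            else:
                out.extend(mod.parameters())
        return out

    def named_group_parameters(self):
        for g in GROUPS:
            if g == "blocks":
                for i, b in enumerate(self.blocks):
                    for name, p in b.named_parameters(f"blocks[{i}]"):
                        yield g, name, p
            else:
                mod = {"stem": self.stem, "fc1": self.fc1, "fc2": self.fc2}[g]
                for name, p in mod.named_parameters(g):
                    yield g, name, p

    # -- forward ---------------------------------------------------------
    def forward(self, X, training: bool = False) -> tuple[Tensor, Tensor]:
        """Run a batch through the network.

        ``X`` may be (n, L) or (n, 1, L).  Returns ``(features, predictions)``
        where features are the post-ReLU first fully connected activations
        (n x 100) and predictions are the raw scalar head outputs (n x 1), on
        the standardised target scale.
        """
        dtype = np.dtype(self.config.dtype)
        arr = X.data if isinstance(X, Tensor) else np.asarray(X)
        if arr.dtype != dtype:
            arr = arr.astype(dtype)
        if arr.ndim == 2:
            arr = arr[:, None, :]
        if self.x_mean is not None:
            arr = (arr - self.x_mean.astype(dtype)) * dtype.type(1.0 / self.x_scale)
        if arr.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channel(s), got {arr.shape[1]}"
            )
        if arr.shape[2] < max(self.config.kernel_sizes):
            raise ValueError("input shorter than the largest branch kernel")
        h = (X.reshape(arr.shape)
             if isinstance(X, Tensor) and X.data.dtype == dtype and self.x_mean is None
             else Tensor(arr))
        h = self.stem(h).relu()
        for blk in self.blocks:
            h = blk(h)
        h = self.pool(h)
        h = self.dropout(h, training=training)
        n = h.data.shape[0]
        flat = h.reshape(n, h.data.shape[1] * h.data.shape[2])
        features = self.fc1(flat).relu()
        predictions = self.fc2(features)
        return features, predictions

    def predict(self, X) -> np.ndarray:
        """Deterministic (eval-mode) predictions on the original target scale."""
        _, preds = self.forward(X, training=False)
        return self.y_mean + self.y_sd * preds.data.ravel().astype(np.float64)

    def se_gates(self, X) -> list[np.ndarray]:
        """Run eval-mode forward and return each block's SE gate matrix."""
        self.forward(X, training=False)
        return [b.se.last_gates for b in self.blocks if hasattr(b, "se")]

    def copy(self) -> "NetworkHandle":
        return copy.deepcopy(self)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for g, name, p in self.named_group_parameters():
            arrays[f"{g}::{name}"] = p.data
        meta = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "block_factory": self.block_factory,
            "y_mean": float(self.y_mean),
            "y_sd": float(self.y_sd),
            "x_scale": float(self.x_scale),
            "has_x_mean": self.x_mean is not None,
        }
        if self.x_mean is not None:
            arrays["__x_mean__"] = self.x_mean
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "NetworkHandle":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            net = cls(ModelConfig.from_dict(meta["config"]), meta["seed"],
                      meta["block_factory"])
            net.y_mean = meta["y_mean"]
            net.y_sd = meta["y_sd"]
            net.x_scale = meta.get("x_scale", 1.0)
            if meta.get("has_x_mean"):
                net.x_mean = z["__x_mean__"].copy()
            stored = {k: z[k] for k in z.files if k not in ("__meta__", "__x_mean__")}
        for g, name, p in net.named_group_parameters():
            key = f"{g}::{name}"
            if key not in stored:
                raise ValueError(f"checkpoint missing parameter {key}")
            if stored[key].shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for {key}")
            p.data = stored[key].copy()
        return net


# ----------------------------------------------------------------------
# Public operations
# ----------------------------------------------------------------------

def build_model(config: ModelConfig, seed: int = 0) -> NetworkHandle:
    """Build the reference network with seed-reproducible initialisation."""
    return NetworkHandle(config, seed, block_factory="rx")


def forward(net: NetworkHandle, batch) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode forward pass returning (features, predictions) as arrays."""
    f, p = net.forward(batch, training=False)
    return f.data, p.data


def count_parameters(net: NetworkHandle, groups=GROUPS) -> int:
    """Exact parameter count over the union of the named groups."""
    return sum(p.data.size for p in net.group_parameters(groups))


def dsc_param_count(in_channels: int, out_channels: int, kernel_size: int,
                    bias: bool = True) -> int:
    """Parameters of a depthwise-separable convolution (depthwise+pointwise)."""
    b_dw = in_channels if bias else 0
    b_pw = out_channels if bias else 0
    return in_channels * kernel_size + b_dw + in_channels * out_channels + b_pw


def standard_conv_param_count(in_channels: int, out_channels: int,
                              kernel_size: int, bias: bool = True) -> int:
    """Parameters of a standard convolution with the same shape."""
    return in_channels * out_channels * kernel_size + (out_channels if bias else 0)
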