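"""Building blocks of the segmentation encoder.

Three units carry the architecture:

* :class:`GhostBlock` — a "ghost" convolution that produces part of its
  output with a full (primary) convolution and the rest with a cheap
  grouped convolution applied to the primary ("intrinsic") maps, cutting
  the parameter count well below a plain convolution of the same width.
* :class:`SwitchableNorm` — a learned softmax mixture of batch-, instance-
  and layer-wise statistics, robust across batch sizes (including 1).
* :class:`MultiHeadSelfAttention2d` — spatial self-attention over feature
  map positions with optional 2-D relative-position logits, used as the
  middle operator of the bottleneck-transformer block.

:class:`ResidualBottleneck` wires either a ghost 3×3 (the residual ghost
bottleneck) or MHSA (the bottleneck transformer) between two point-wise
ghost blocks, with a normalization after each and a residual shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Module,
    Parameter,
    Tensor,
    concatenate,
    conv2d,
    relu,
    softmax,
)

__all__ = [
    "SwitchableNorm",
    "BatchNorm2d",
    "GhostBlock",
    "PlainConvBlock",
    "MultiHeadSelfAttention2d",
    "AttentionOutput",
    "ResidualBottleneck",
    "ghost_param_count",
    "plain_conv_param_count",
]


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class SwitchableNorm(Module):
    """Switchable normalization over a (B, C, H, W) feature map.

    Per-location statistics are mixed from three normalizers — batch norm
    (per channel over batch and space), instance norm (per sample and
    channel over space) and layer norm (per sample over channels and
    space) — with separate softmax importance weights for the mean and the
    variance. Batch statistics are replaced by running averages at
    inference time; instance and layer statistics are always computed from
    the input, so the layer stays well defined at batch size 1.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        # order: (BN, IN, LN); zero logits start as an unbiased mixture
        self.mean_logits = Parameter(np.zeros(3))
        self.var_logits = Parameter(np.zeros(3))
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def _buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[0] < 1:
            raise ValueError("switchable norm requires batch size >= 1")
        if x.shape[1] != self.channels:
            raise ValueError(
                f"switchable norm built for {self.channels} channels, got {x.shape[1]}"
            )
        mu_in = x.mean(axis=(2, 3), keepdims=True)  # (B,C,1,1)
        var_in = ((x - mu_in) ** 2).mean(axis=(2, 3), keepdims=True)
        # layer stats follow from the instance stats exactly
        mu_ln = mu_in.mean(axis=1, keepdims=True)
        var_ln = (var_in + mu_in ** 2).mean(axis=1, keepdims=True) - mu_ln ** 2
        if self.training:
            mu_bn = mu_in.mean(axis=0, keepdims=True)
            var_bn = (var_in + mu_in ** 2).mean(axis=0, keepdims=True) - mu_bn ** 2
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu_bn.data
            self.running_var *= 1 - m
            self.running_var += m * var_bn.data
        else:
            mu_bn = Tensor(self.running_mean)
            var_bn = Tensor(self.running_var)
        wm = softmax(self.mean_logits, axis=0)
        wv = softmax(self.var_logits, axis=0)
        mu = wm[0] * mu_bn + wm[1] * mu_in + wm[2] * mu_ln
        var = wv[0] * var_bn + wv[1] * var_in + wv[2] * var_ln
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return self.gamma * xhat + self.beta


class BatchNorm2d(Module):
    """Plain batch normalization (the ablation alternative to switchable norm)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def _buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[0] < 1:
            raise ValueError("batch norm requires batch size >= 1")
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data
            self.running_var *= 1 - m
            self.running_var += m * var.data
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        return self.gamma * ((x - mu) * (var + self.eps) ** -0.5) + self.beta


def make_norm(kind: str, channels: int) -> Module:
    if kind == "SN":
        return SwitchableNorm(channels)
    if kind == "BN":
        return BatchNorm2d(channels)
    raise ValueError(f"unknown normalizer {kind!r} (expected 'SN' or 'BN')")


# -- ghost convolution --------------------------------------------------


def ghost_param_count(
    in_channels: int,
    out_channels: int,
    ratio: int = 2,
    primary_kernel: int = 1,
    cheap_kernel: int = 3,
) -> int:
    """Closed-form weight count of a (bias-free) ghost block."""
    intrinsic = math.ceil(out_channels / ratio)
    new = intrinsic * (ratio - 1)
    return in_channels * intrinsic * primary_kernel ** 2 + new * cheap_kernel ** 2


def plain_conv_param_count(in_channels: int, out_channels: int, kernel: int = 3) -> int:
    return in_channels * out_channels * kernel ** 2


class GhostBlock(Module):
    """Ghost convolution: primary conv for intrinsic maps + cheap grouped conv.

    ``intrinsic = ceil(out/ratio)`` maps come from the primary convolution
    (point-wise by default); the remaining ``out - intrinsic`` "ghost" maps
    come from a ``cheap_kernel`` grouped convolution with one group per
    intrinsic map. A stride, when given, is applied by the primary
    convolution; the cheap operation always runs at stride 1 on the
    already-downsampled intrinsic maps. Convolutions are bias-free (the
    following normalization supplies the shift) and use "same" padding.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ratio: int = 2,
        primary_kernel: int = 1,
        cheap_kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if ratio < 2:
            raise ValueError(f"ghost ratio must be >= 2, got {ratio}")
        if primary_kernel % 2 == 0 or cheap_kernel % 2 == 0:
            raise ValueError("ghost kernels must be odd for 'same' padding")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ratio = ratio
        self.primary_kernel = primary_kernel
        self.cheap_kernel = cheap_kernel
        self.stride = stride
        self.intrinsic = math.ceil(out_channels / ratio)
        self.cheap = out_channels - self.intrinsic
        fan_p = in_channels * primary_kernel ** 2
        self.primary_weight = Parameter(
            he_uniform(rng, (self.intrinsic, in_channels, primary_kernel, primary_kernel), fan_p)
        )
        n_new = self.intrinsic * (ratio - 1)  # >= cheap; sliced when out % ratio != 0
        self.cheap_weight = Parameter(
            he_uniform(rng, (n_new, 1, cheap_kernel, cheap_kernel), cheap_kernel ** 2)
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"ghost block expects {self.in_channels} input channels, "
                f"got {x.shape[1]}"
            )
        if self.stride > 1 and (x.shape[2] % self.stride or x.shape[3] % self.stride):
            raise ValueError(
                f"spatial dims {x.shape[2:]} not divisible by stride {self.stride}"
            )
        intrinsic = conv2d(
            x,
            self.primary_weight,
            stride=self.stride,
            padding=self.primary_kernel // 2,
        )
        ghost = conv2d(
            intrinsic,
            self.cheap_weight,
            padding=self.cheap_kernel // 2,
            groups=self.intrinsic,
        )
        if ghost.shape[1] != self.cheap:
            ghost = ghost[:, : self.cheap]
        return concatenate([intrinsic, ghost], axis=1)

    def param_count(self) -> int:
        return self.primary_weight.data.size + self.cheap_weight.data.size


class PlainConvBlock(Module):
    """Plain (bias-free) convolution, the parameter-count baseline for GhostBlock."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.weight = Parameter(
            he_uniform(rng, (out_channels, in_channels, kernel, kernel), in_channels * kernel ** 2)
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, stride=self.stride, padding=self.kernel // 2)

    def param_count(self) -> int:
        return self.weight.data.size


# -- multi-head self-attention ------------------------------------------


@dataclass
class AttentionOutput:
    """MHSA result: output feature map and per-head attention weights."""

    output: Tensor
    weights: np.ndarray  # (batch, heads, H*W, H*W); each row sums to 1


class MultiHeadSelfAttention2d(Module):
    """Multi-head self-attention over the spatial positions of a feature map.

    Queries, keys and values are 1×1 projections; logits are the scaled
    dot products q·k/sqrt(head_dim), plus learned 2-D relative-position
    logits (a per-head table over row offsets plus one over column
    offsets) when enabled. Relative tables are sized to a fixed spatial
    extent, so inputs of any other size are rejected rather than silently
    interpolated.
    """

    def __init__(
        self,
        channels: int,
        heads: int = 4,
        spatial: tuple[int, int] | None = None,
        use_relative_positions: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if channels % heads != 0:
            raise ValueError(
                f"heads ({heads}) must divide channels ({channels})"
            )
        if use_relative_positions and spatial is None:
            raise ValueError("relative positions require a fixed spatial size")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.heads = heads
        self.head_dim = channels // heads
        self.spatial = tuple(spatial) if spatial is not None else None
        self.use_relative_positions = use_relative_positions
        w = lambda: Parameter(he_uniform(rng, (channels, channels, 1, 1), channels))
        self.wq, self.wk, self.wv, self.wo = w(), w(), w(), w()
        if use_relative_positions:
            H, W = self.spatial
            self.rel_rows = Parameter(rng.normal(0.0, 0.02, (heads, 2 * H - 1)))
            self.rel_cols = Parameter(rng.normal(0.0, 0.02, (heads, 2 * W - 1)))

    def _relative_logits(self, H: int, W: int) -> Tensor:
        rows = np.arange(H * W) // W
        cols = np.arange(H * W) % W
        d_row = rows[:, None] - rows[None, :] + H - 1  # (L, L) in [0, 2H-2]
        d_col = cols[:, None] - cols[None, :] + W - 1
        bias = self.rel_rows[:, d_row] + self.rel_cols[:, d_col]  # (heads, L, L)
        return bias

    def forward(self, x: Tensor, return_attention: bool = False):
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"MHSA built for {self.channels} channels, got {C}")
        if self.use_relative_positions and (H, W) != self.spatial:
            raise ValueError(
                f"MHSA relative tables sized for {self.spatial}, got {(H, W)}"
            )
        L, h, d = H * W, self.heads, self.head_dim
        q = conv2d(x, self.wq).reshape(B, h, d, L).transpose(0, 1, 3, 2)
        k = conv2d(x, self.wk).reshape(B, h, d, L)
        v = conv2d(x, self.wv).reshape(B, h, d, L).transpose(0, 1, 3, 2)
        logits = (q @ k) * (1.0 / math.sqrt(d))  # (B, h, L, L)
        if self.use_relative_positions:
            logits = logits + self._relative_logits(H, W).reshape(1, h, L, L)
        attn = softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 1, 3, 2).reshape(B, C, H, W)
        out = conv2d(out, self.wo)
        if return_attention:
            return AttentionOutput(output=out, weights=attn.data)
        return out


# -- residual bottlenecks -----------------------------------------------


class ResidualBottleneck(Module):
    """Residual bottleneck with ghost blocks and a switchable middle operator.

    Main path: point-wise ghost block reducing to ``out/reduction`` →
    norm → ReLU → middle operator (ghost 3×3 with the block's stride, or
    MHSA at stride 1) → norm → ReLU → point-wise ghost block expanding to
    ``out`` → norm. The shortcut is the identity when shapes match,
    otherwise a strided 1×1 projection with its own norm. A final ReLU
    follows the residual sum.

    ``middle='ghost'`` gives the residual ghost bottleneck used by the
    encoder stages; ``middle='mhsa'`` gives the bottleneck transformer.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        middle: str = "ghost",
        normalizer: str = "SN",
        ghost_ratio: int = 2,
        reduction: int = 4,
        heads: int = 4,
        spatial: tuple[int, int] | None = None,
        use_relative_positions: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        if middle not in ("ghost", "mhsa"):
            raise ValueError(f"unknown middle operator {middle!r}")
        if middle == "mhsa" and stride != 1:
            raise ValueError("the transformer bottleneck requires stride 1")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.middle_kind = middle
        mid = max(out_channels // reduction, 1)
        self.mid_channels = mid
        self.reduce = GhostBlock(in_channels, mid, ratio=ghost_ratio, rng=rng)
        self.norm1 = make_norm(normalizer, mid)
        if middle == "ghost":
            self.middle = GhostBlock(
                mid, mid, ratio=ghost_ratio, primary_kernel=3, stride=stride, rng=rng
            )
        else:
            self.middle = MultiHeadSelfAttention2d(
                mid,
                heads=heads,
                spatial=spatial,
                use_relative_positions=use_relative_positions,
                rng=rng,
            )
        self.norm2 = make_norm(normalizer, mid)
        self.expand = GhostBlock(mid, out_channels, ratio=ghost_ratio, rng=rng)
        self.norm3 = make_norm(normalizer, out_channels)
        if in_channels != out_channels or stride != 1:
            self.shortcut_weight = Parameter(
                he_uniform(rng, (out_channels, in_channels, 1, 1), in_channels)
            )
            self.shortcut_norm = make_norm(normalizer, out_channels)
        else:
            self.shortcut_weight = None
            self.shortcut_norm = None

    def forward(self, x: Tensor) -> Tensor:
        if self.stride == 2 and (x.shape[2] % 2 or x.shape[3] % 2):
            raise ValueError(
                f"stride-2 bottleneck requires even spatial dims, got {x.shape[2:]}"
            )
        h = relu(self.norm1(self.reduce(x)))
        h = relu(self.norm2(self.middle(h)))
        h = self.norm3(self.expand(h))
        if self.shortcut_weight is not None:
            s = conv2d(x, self.shortcut_weight, stride=self.stride)
            s = self.shortcut_norm(s)
        else:
            s = x
        return relu(h + s)
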