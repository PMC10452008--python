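"""The hybrid U-Net: ghost-bottleneck encoder with a transformer stage.

Encoder (four halvings): a two-convolution stem at full resolution, then
stage 1 = 3×3/stride-2 max pooling + one residual ghost bottleneck,
stages 2–3 = two and three stacked bottlenecks (first of each strided),
and stage 4 = a bottleneck transformer followed by 2×2 average pooling.
Skip features are captured at full, 1/2, 1/4 and 1/8 resolution; the
bottleneck sits at 1/16.

Decoder: four "TRCCR" units — transposed convolution (stride 2), ReLU,
concatenation with the matching skip, 1×1 convolution, ReLU — followed by
a 1×1 head producing per-pixel class scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import (
    Module,
    Parameter,
    Tensor,
    avgpool2d,
    concatenate,
    conv2d,
    conv_transpose2d,
    maxpool2d,
    no_grad,
    relu,
    softmax,
)
from .core_blocks import (
    GhostBlock,
    PlainConvBlock,
    ResidualBottleneck,
    he_uniform,
    make_norm,
)

__all__ = [
    "NetworkConfig",
    "EncoderOutput",
    "Encoder",
    "Decoder",
    "GhostBoTUNet",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "CPU_SMALL",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``patch_size`` fixes the training resolution; the MHSA relative-position
    tables are sized to ``patch_size/8`` (the transformer stage's input
    resolution), so inference inputs must match it. ``normalizer`` selects
    switchable normalization ("SN", default) or plain batch normalization
    ("BN", the ablation variant).
    """

    in_channels: int = 3
    num_classes: int = 2
    stem_width: int = 64
    stage_widths: tuple[int, ...] = (128, 256, 512, 1024)
    rgs_depths: tuple[int, ...] = (1, 2, 3)
    mhsa_heads: int = 4
    ghost_ratio: int = 2
    normalizer: str = "SN"
    use_relative_positions: bool = True
    patch_size: int = 512

    def __post_init__(self):
        self.stage_widths = tuple(self.stage_widths)
        self.rgs_depths = tuple(self.rgs_depths)
        if len(self.stage_widths) != 4:
            raise ValueError("stage_widths must have exactly 4 entries")
        if len(self.rgs_depths) != 3:
            raise ValueError("rgs_depths must have exactly 3 entries")
        if self.stage_widths[3] // 4 % self.mhsa_heads != 0:
            raise ValueError(
                f"mhsa_heads ({self.mhsa_heads}) must divide the transformer "
                f"width ({self.stage_widths[3] // 4})"
            )
        if self.patch_size % 16 != 0:
            raise ValueError("patch_size must be divisible by 16 (four halvings)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        return cls(**json.loads(s))


#: Width-reduced profile for desk-scale CPU training and testing.
CPU_SMALL = dict(stem_width=8, stage_widths=(16, 32, 64, 128), patch_size=64)


@dataclass
class EncoderOutput:
    """Skip features at 1, 1/2, 1/4, 1/8 resolution plus the 1/16 bottleneck."""

    skips: list[Tensor]
    bottleneck: Tensor


class _ConvNormRelu(Module):
    def __init__(self, cin, cout, kernel, normalizer, rng):
        super().__init__()
        self.weight = Parameter(
            he_uniform(rng, (cout, cin, kernel, kernel), cin * kernel * kernel)
        )
        self.kernel = kernel
        self.norm = make_norm(normalizer, cout)

    def forward(self, x):
        return relu(self.norm(conv2d(x, self.weight, padding=self.kernel // 2)))


class Encoder(Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w0 = cfg.stem_width
        w1, w2, w3, w4 = cfg.stage_widths
        self.stem = [
            _ConvNormRelu(cfg.in_channels, w0, 3, cfg.normalizer, rng),
            _ConvNormRelu(w0, w0, 3, cfg.normalizer, rng),
        ]

        def rgs(cin, cout, stride):
            return ResidualBottleneck(
                cin,
                cout,
                stride=stride,
                middle="ghost",
                normalizer=cfg.normalizer,
                ghost_ratio=cfg.ghost_ratio,
                rng=rng,
            )

        d1, d2, d3 = cfg.rgs_depths
        # stage 1: the max pooling downsamples, the bottlenecks keep stride 1
        self.stage1 = [rgs(w0 if i == 0 else w1, w1, 1) for i in range(d1)]
        self.stage2 = [rgs(w1 if i == 0 else w2, w2, 2 if i == 0 else 1) for i in range(d2)]
        self.stage3 = [rgs(w2 if i == 0 else w3, w3, 2 if i == 0 else 1) for i in range(d3)]
        bot_res = cfg.patch_size // 8
        self.stage4 = ResidualBottleneck(
            w3,
            w4,
            stride=1,
            middle="mhsa",
            normalizer=cfg.normalizer,
            ghost_ratio=cfg.ghost_ratio,
            heads=cfg.mhsa_heads,
            spatial=(bot_res, bot_res),
            use_relative_positions=cfg.use_relative_positions,
            rng=rng,
        )

    def forward(self, x: Tensor) -> EncoderOutput:
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} must be divisible by 16"
            )
        h = x
        for layer in self.stem:
            h = layer(h)
        skips = [h]  # full resolution
        h = maxpool2d(h, kernel=3, stride=2, padding=1)
        for block in self.stage1:
            h = block(h)
        skips.append(h)  # 1/2
        for block in self.stage2:
            h = block(h)
        skips.append(h)  # 1/4
        for block in self.stage3:
            h = block(h)
        skips.append(h)  # 1/8
        h = self.stage4(h)
        h = avgpool2d(h, kernel=2, stride=2)  # 1/16
        return EncoderOutput(skips=skips, bottleneck=h)


class _UpUnit(Module):
    """TRCCR decoder unit: Tconv → ReLU → concat skip → 1×1 conv → ReLU."""

    def __init__(self, cin, skip_ch, cout, rng):
        super().__init__()
        self.up_weight = Parameter(he_uniform(rng, (cin, cout, 2, 2), cin))
        self.up_bias = Parameter(np.zeros(cout))
        self.mix_weight = Parameter(
            he_uniform(rng, (cout, cout + skip_ch, 1, 1), cout + skip_ch)
        )
        self.mix_bias = Parameter(np.zeros(cout))
        self.skip_ch = skip_ch

    def forward(self, x: Tensor, skip: Tensor, stage: int) -> Tensor:
        h = relu(conv_transpose2d(x, self.up_weight, self.up_bias, stride=2))
        if h.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"decoder stage {stage}: upsampled resolution {h.shape[2:]} does "
                f"not match skip resolution {skip.shape[2:]}"
            )
        h = concatenate([h, skip], axis=1)
        return relu(conv2d(h, self.mix_weight, self.mix_bias))


class Decoder(Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        w0 = cfg.stem_width
        w1, w2, w3, w4 = cfg.stage_widths
        # each unit maps (upsampled + skip) down to the encoder width below
        self.units = [
            _UpUnit(w4, w3, w3, rng),
            _UpUnit(w3, w2, w2, rng),
            _UpUnit(w2, w1, w1, rng),
            _UpUnit(w1, w0, w0, rng),
        ]

    def forward(self, enc: EncoderOutput) -> Tensor:
        h = enc.bottleneck
        for stage, (unit, skip) in enumerate(zip(self.units, reversed(enc.skips)), 1):
            h = unit(h, skip, stage)
        return h


class GhostBoTUNet(Module):
    """Encoder–decoder segmentation network with a 1×1 classification head."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.head_weight = Parameter(
            he_uniform(rng, (cfg.num_classes, cfg.stem_width, 1, 1), cfg.stem_width)
        )
        self.head_bias = Parameter(np.zeros(cfg.num_classes))

    def forward(self, x: Tensor) -> Tensor:
        """Per-pixel class scores, shape (batch, num_classes, H, W)."""
        h = self.decoder(self.encoder(x))
        return conv2d(h, self.head_weight, self.head_bias)

    def predict_proba(self, x: Tensor) -> Tensor:
        """Per-pixel class probabilities (softmax over the class axis)."""
        return softmax(self.forward(x), axis=1)

    def predict_foreground(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability map for a (B,3,H,W) array, inference mode."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                proba = self.predict_proba(Tensor(x))
        finally:
            self.train(was_training)
        return proba.data[:, 1]


def build_model(
    cfg: NetworkConfig, seed: int | None = None, plain_conv: bool = False
) -> GhostBoTUNet:
    """Construct a seeded model; ``plain_conv`` swaps every ghost block for a
    plain convolution of the same geometry (the parameter-count baseline)."""
    rng = np.random.default_rng(seed)
    model = GhostBoTUNet(cfg, rng)
    if plain_conv:
        for mod in model.modules():
            if isinstance(mod, ResidualBottleneck):
                for name in ("reduce", "middle", "expand"):
                    blk = getattr(mod, name)
                    if isinstance(blk, GhostBlock):
                        setattr(
                            mod,
                            name,
                            PlainConvBlock(
                                blk.in_channels,
                                blk.out_channels,
                                kernel=max(blk.primary_kernel, blk.cheap_kernel),
                                stride=blk.stride,
                                rng=rng,
                            ),
                        )
    return model


def count_parameters(model: Module) -> dict:
    """Total learnable scalar count, with a per-module-group breakdown."""
    groups: dict[str, int] = {}
    if isinstance(model, GhostBoTUNet):
        groups["encoder"] = sum(p.data.size for p in model.encoder.parameters())
        groups["decoder"] = sum(p.data.size for p in model.decoder.parameters())
        groups["head"] = model.head_weight.data.size + model.head_bias.data.size
    total = sum(p.data.size for p in model.parameters())
    return {"total": int(total), **{k: int(v) for k, v in groups.items()}}


def save_checkpoint(model: GhostBoTUNet, path) -> None:
    """Weights + config in one npz; the config round-trips losslessly."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=np.frombuffer(model.cfg.to_json().encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> GhostBoTUNet:
    with np.load(path) as data:
        cfg = NetworkConfig.from_json(bytes(data["config"]).decode())
        n = len([k for k in data.files if k.startswith("arr_")])
        arrays = [data[f"arr_{i}"] for i in range(n)]
    model = GhostBoTUNet(cfg)
    model.load_state_arrays(arrays)
    return model
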