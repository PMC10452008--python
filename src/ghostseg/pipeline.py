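"""Training, inference and evaluation orchestration.

Defaults follow the reference training recipe: SGD (momentum 0.9, weight
decay 1e-4), learning rate 1e-2, batch size 2, 500 epochs, 512×512 patches
dense-cropped at stride 512, 4 attention heads, class-wise dice loss. The
``cpu-small`` profile shrinks only the widths/patch size/epoch count so the
same pipeline runs at desk scale on one CPU.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import data_synth, metrics
from .autodiff import SGD, Tensor
from .data_synth import PatchRecord, augment, dense_crop, read_image, read_mask, stitch
from .losses import class_wise_dice_loss, dice_loss
from .network import (
    CPU_SMALL,
    GhostBoTUNet,
    NetworkConfig,
    build_model,
    save_checkpoint,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "predict",
    "evaluate",
    "load_records",
]


@dataclass
class TrainConfig:
    """Full training recipe; the defaults are the reference hyperparameters."""

    optimizer: str = "SGD"
    learning_rate: float = 1.0e-2
    weight_decay: float = 1.0e-4
    momentum: float = 0.9
    batch_size: int = 2
    epochs: int = 500
    patch_size: int = 512
    crop_stride: int = 512
    mhsa_heads: int = 4
    seed: int = 0
    profile: str = "full"  # "full" or "cpu-small"
    loss: str = "CDL"  # "CDL" or "dice"
    lr_schedule: str = "constant"  # "constant" or "cosine"
    ghost_ratio: int = 2
    normalizer: str = "SN"
    use_relative_positions: bool = True
    positives_only: bool = False
    augment_data: bool = True
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.optimizer != "SGD":
            raise ValueError("only SGD is supported")
        if self.loss not in ("CDL", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.profile not in ("full", "cpu-small"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "cpu-small":
            self.patch_size = min(self.patch_size, CPU_SMALL["patch_size"])

    def network_config(self) -> NetworkConfig:
        kw = dict(
            mhsa_heads=self.mhsa_heads,
            ghost_ratio=self.ghost_ratio,
            normalizer=self.normalizer,
            use_relative_positions=self.use_relative_positions,
            patch_size=self.patch_size,
        )
        if self.profile == "cpu-small":
            kw.update(
                stem_width=CPU_SMALL["stem_width"],
                stage_widths=CPU_SMALL["stage_widths"],
            )
        return NetworkConfig(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)  # one record per completed epoch
    events: list = field(default_factory=list)

    def log(self, message: str):
        self.events.append(message)

    def to_json(self) -> str:
        return json.dumps({"epochs": self.epochs, "events": self.events}, indent=2)


def load_records(manifest_path) -> list[PatchRecord]:
    """Load a tab-separated manifest (image, mask, label) into memory."""
    records = []
    for image_path, mask_path, label in data_synth.read_manifest(manifest_path):
        image = read_image(image_path)
        mask = None if mask_path == "-" else read_mask(mask_path)
        records.append(
            PatchRecord(image, mask, int(label) if mask is None else int(mask.any()))
        )
    return records


def _to_input(images: np.ndarray) -> np.ndarray:
    """(B, H, W, 3) uint8 -> (B, 3, H, W) float in [0, 1]."""
    return images.astype(np.float64).transpose(0, 3, 1, 2) / 255.0


def _train_dsc(model: GhostBoTUNet, records, batch_size: int) -> float:
    """Mean DSC of thresholded predictions over a set of records.

    Uses the same aggregation convention as :func:`ghostseg.metrics
    .evaluate_testset`: DSC is averaged over patches with a nonempty
    annotation (on empty annotations the dice is an all-or-nothing 0/1 and
    negative patches are instead judged by the classification metrics).
    Falls back to the empty-empty convention when no patch is positive.
    """
    positive, negative = [], []
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        x = _to_input(np.stack([r.image for r in chunk]))
        fg = model.predict_foreground(x)
        for rec, prob in zip(chunk, fg):
            score = metrics.dsc(rec.mask, (prob >= 0.5).astype(np.uint8))
            (positive if rec.label else negative).append(score)
    return float(np.mean(positive if positive else negative))


def train(
    cfg: TrainConfig,
    records: list[PatchRecord],
    val_records: list[PatchRecord] | None = None,
    max_steps: int | None = None,
    stop_train_dsc: float | None = None,
    eval_every: int = 1,
    checkpoint_path=None,
) -> tuple[GhostBoTUNet, TrainHistory]:
    """Seeded training run; returns the best-validation-DSC model.

    ``records`` are in-memory patches (use :func:`load_records` for a
    manifest). Without ``val_records``, ``cfg.val_fraction`` of the records
    (at least one, when positive) is held out for model selection; with
    ``val_fraction=0`` the final model is returned. ``max_steps`` caps the
    number of optimizer updates; ``stop_train_dsc`` stops early once the
    training-set DSC (checked every ``eval_every`` epochs) reaches the
    target.
    """
    if not records:
        raise ValueError("empty training dataset")
    for rec in records:
        if rec.mask is None:
            raise ValueError("training records need masks")
        if rec.image.shape[0] != cfg.patch_size or rec.image.shape[1] != cfg.patch_size:
            raise ValueError(
                f"patch shape {rec.image.shape[:2]} does not match configured "
                f"patch size {cfg.patch_size}"
            )
    if cfg.positives_only:
        records = [r for r in records if r.label == 1]
        if not records:
            raise ValueError("positives_only left no training records")
    rng = np.random.default_rng(cfg.seed)
    if val_records is None and cfg.val_fraction > 0 and len(records) > 1:
        n_val = max(1, int(round(cfg.val_fraction * len(records))))
        order = rng.permutation(len(records))
        val_records = [records[i] for i in order[:n_val]]
        records = [records[i] for i in order[n_val:]]

    model = build_model(cfg.network_config(), seed=cfg.seed)
    params = model.parameters()
    opt = SGD(
        params,
        lr=cfg.learning_rate,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
    )
    total_steps = max_steps or cfg.epochs * math.ceil(len(records) / cfg.batch_size)
    history = TrainHistory()
    history.log(f"resolved config: {json.dumps(cfg.to_dict(), sort_keys=True)}")
    history.log(f"training on {len(records)} patches"
                + (f", validating on {len(val_records)}" if val_records else ""))
    loss_fn = class_wise_dice_loss if cfg.loss == "CDL" else dice_loss

    best_val = -1.0
    best_state = None
    step = 0
    t0 = time.time()
    for epoch in range(cfg.epochs):
        if max_steps is not None and step >= max_steps:
            break
        model.train()
        order = rng.permutation(len(records))
        losses = []
        for start in range(0, len(records), cfg.batch_size):
            if max_steps is not None and step >= max_steps:
                break
            batch = [records[i] for i in order[start : start + cfg.batch_size]]
            if cfg.augment_data:
                batch = [
                    augment(r, int(rng.integers(2 ** 31))) for r in batch
                ]
            x = Tensor(_to_input(np.stack([r.image for r in batch])))
            y = np.stack([r.mask for r in batch]).astype(np.float64)
            if cfg.lr_schedule == "cosine":
                opt.lr = cfg.learning_rate * 0.5 * (1 + math.cos(math.pi * step / total_steps))
            proba = model.predict_proba(x)
            fg = proba[:, 1]
            loss = loss_fn(fg, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
        record = {"epoch": epoch + 1, "step": step, "loss": float(np.mean(losses))}
        if (epoch + 1) % eval_every == 0 or step >= total_steps:
            model.eval()
            record["train_dsc"] = _train_dsc(model, records, cfg.batch_size)
            if val_records:
                record["val_dsc"] = _train_dsc(model, val_records, cfg.batch_size)
                if record["val_dsc"] > best_val:
                    best_val = record["val_dsc"]
                    best_state = [a.copy() for a in model.state_arrays()]
                    history.log(
                        f"epoch {epoch + 1}: new best validation DSC {best_val:.4f}"
                    )
        history.epochs.append(record)
        if stop_train_dsc is not None and record.get("train_dsc", 0.0) >= stop_train_dsc:
            history.log(
                f"early stop at step {step}: train DSC {record['train_dsc']:.4f} "
                f">= {stop_train_dsc}"
            )
            break
    history.log(f"finished {step} steps in {time.time() - t0:.1f}s")
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
        history.log(f"checkpoint written to {checkpoint_path}")
    return model, history


def predict(
    model: GhostBoTUNet,
    images: list[np.ndarray],
    threshold: float = 0.5,
    stitch_patches: bool = True,
    crop_stride: int | None = None,
) -> list[np.ndarray]:
    """Segment full images: dense-crop, run the network, binarize, stitch.

    Each image is tiled to the model's configured patch size, per-patch
    foreground probabilities are thresholded at ``threshold``, and patch
    masks are stitched back (logical OR on overlaps). With
    ``stitch_patches=False`` a list of per-patch masks is returned per image
    instead of one full-size mask.
    """
    ps = model.cfg.patch_size
    stride = crop_stride or ps
    results = []
    for image in images:
        patches = dense_crop(image, None, patch_size=ps, stride=stride)
        masks = []
        for rec in patches:
            x = _to_input(rec.image[None])
            prob = model.predict_foreground(x)[0]
            masks.append((prob >= threshold).astype(np.uint8))
        if stitch_patches:
            results.append(stitch(patches, image.shape[:2], masks=masks))
        else:
            results.append(masks)
    return results


def evaluate(
    model: GhostBoTUNet,
    records: list[PatchRecord],
    threshold: float = 0.5,
    positive_fraction_threshold: float = 1e-3,
) -> metrics.MetricsReport:
    """Predict every test record and aggregate the six-column report."""
    for rec in records:
        if rec.mask is None:
            raise ValueError("evaluation records need annotation masks")
    preds = predict(model, [r.image for r in records], threshold=threshold)
    return metrics.evaluate_testset(
        preds,
        [r.mask for r in records],
        [r.label for r in records],
        positive_fraction_threshold=positive_fraction_threshold,
    )
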