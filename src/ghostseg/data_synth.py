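"""Patch extraction, mask I/O, augmentation, and synthetic H&E-like data.

Large tissue images are tiled by dense cropping (a fixed-stride grid with
edge-anchored final rows/columns so every pixel is covered) and patch
predictions are stitched back by logical OR (recall-preserving) or by
averaging. Masks follow the 8-bit PNG convention 0 = background,
255 = foreground.

The synthetic generator emulates the look of H&E-stained tissue patches —
a pink textured background with purple blob-shaped lesion regions — paired
with exact masks and image-level lesion labels, so the whole training and
evaluation pipeline is exercisable without any pathology download. All
randomness flows from explicit (seed, index) pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

__all__ = [
    "PatchRecord",
    "SynthParams",
    "dense_crop",
    "stitch",
    "synthesize_sample",
    "synthesize_dataset",
    "augment",
    "apply_dihedral",
    "read_mask",
    "write_mask",
    "read_image",
    "write_manifest",
    "read_manifest",
]


@dataclass(eq=False)
class PatchRecord:
    """An RGB patch with its binary mask, lesion label and source origin."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray | None = None  # (H, W) in {0, 1}
    label: int = 0  # 1 iff the mask contains foreground
    origin: tuple[int, int] = (0, 0)  # 0-based (row, col) of the top-left pixel

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.mask is not None:
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"image {self.image.shape[:2]}"
                )
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask must be binary (0/1)")
            expected = int(self.mask.any())
            if self.label != expected:
                raise ValueError(
                    f"label {self.label} inconsistent with mask "
                    f"(foreground present: {bool(expected)})"
                )


def _grid(size: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def dense_crop(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    patch_size: int = 512,
    stride: int = 512,
) -> list[PatchRecord]:
    """Tile an image into a fixed-stride grid of patches with full coverage.

    The final row/column of the grid is anchored at the image edge, so every
    source pixel lands in at least one patch for any stride <= patch_size.
    """
    H, W = image.shape[:2]
    if H < patch_size or W < patch_size:
        raise ValueError(
            f"image {H}x{W} smaller than patch size {patch_size}"
        )
    if mask is not None and mask.shape[:2] != (H, W):
        raise ValueError("mask shape does not match image")
    records = []
    for r in _grid(H, patch_size, stride):
        for c in _grid(W, patch_size, stride):
            img = image[r : r + patch_size, c : c + patch_size]
            if mask is not None:
                m = mask[r : r + patch_size, c : c + patch_size]
                records.append(
                    PatchRecord(img, m, int(m.any()), (r, c))
                )
            else:
                records.append(PatchRecord(img, None, 0, (r, c)))
    return records


def stitch(patches, full_shape, masks=None, rule: str = "or") -> np.ndarray:
    """Reassemble patch masks into a full-size binary mask.

    ``masks`` optionally overrides each record's stored mask (e.g. model
    predictions for the cropped records). Overlaps are resolved by logical
    OR (default) or by averaging followed by a 0.5 threshold
    (``rule="mean"``). Raises if any pixel of ``full_shape`` is uncovered.
    """
    if rule not in ("or", "mean"):
        raise ValueError(f"unknown stitch rule {rule!r}")
    patches = list(patches)
    if masks is None:
        masks = [p.mask for p in patches]
    acc = np.zeros(full_shape, dtype=float)
    count = np.zeros(full_shape, dtype=np.int64)
    for p, m in zip(patches, masks):
        if m is None:
            raise ValueError(f"patch at origin {p.origin} has no mask to stitch")
        r, c = p.origin
        h, w = m.shape
        count[r : r + h, c : c + w] += 1
        if rule == "or":
            acc[r : r + h, c : c + w] = np.maximum(acc[r : r + h, c : c + w], m)
        else:
            acc[r : r + h, c : c + w] += m
    if (count == 0).any():
        first = tuple(int(v) for v in np.argwhere(count == 0)[0])
        raise ValueError(f"stitch coverage gap: pixel {first} never written")
    if rule == "mean":
        return (acc / count >= 0.5).astype(np.uint8)
    return (acc > 0).astype(np.uint8)


@dataclass
class SynthParams:
    """Knobs of the synthetic H&E-like patch generator.

    Defaults draw 512×512 patches (the training patch geometry), half of
    them lesion-positive, with 1–4 purple lesion blobs of 30–140 px radius
    on a pink textured background.
    """

    canvas_size: int = 512
    lesion_probability: float = 0.5
    blob_count: tuple[int, int] = (1, 4)
    blob_radius: tuple[float, float] = (30.0, 140.0)
    background_mean: tuple[float, float, float] = (228.0, 192.0, 214.0)
    foreground_mean: tuple[float, float, float] = (148.0, 94.0, 166.0)
    noise_scale: float = 12.0
    texture_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.blob_count[0] > self.blob_count[1] or self.blob_count[0] < 1:
            raise ValueError("blob_count range must be non-degenerate and >= 1")
        if self.blob_radius[0] >= self.blob_radius[1] or self.blob_radius[0] <= 0:
            raise ValueError("blob_radius range must be non-degenerate and positive")


def _texture(rng, shape, mean, noise_scale, sigma):
    """Low-frequency colour texture plus per-pixel noise around `mean`."""
    base = np.empty(shape + (3,))
    for ch in range(3):
        low = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma)
        low *= noise_scale / max(low.std(), 1e-9)
        base[..., ch] = mean[ch] + low + rng.normal(0.0, noise_scale * 0.5, shape)
    return base


def synthesize_sample(params: SynthParams, index: int) -> PatchRecord:
    """Draw sample `index` of the stream defined by ``params.seed``.

    Deterministic in (seed, index): each sample gets its own child RNG, so
    any sample can be regenerated without drawing its predecessors.
    """
    rng = np.random.default_rng([params.seed, index])
    n = params.canvas_size
    mask = np.zeros((n, n), dtype=np.uint8)
    if rng.random() < params.lesion_probability:
        count = int(rng.integers(params.blob_count[0], params.blob_count[1] + 1))
        for _ in range(count):
            r0, c0 = rng.uniform(0, n, size=2)
            ra, rb = rng.uniform(*params.blob_radius, size=2)
            rot = rng.uniform(0, math.pi)
            rr, cc = ellipse(r0, c0, ra, rb, shape=(n, n), rotation=rot)
            mask[rr, cc] = 1
    img = _texture(
        rng, (n, n), params.background_mean, params.noise_scale, params.texture_sigma
    )
    fg = _texture(
        rng, (n, n), params.foreground_mean, params.noise_scale, params.texture_sigma
    )
    img[mask == 1] = fg[mask == 1]
    img = np.clip(img, 0, 255).astype(np.uint8)
    return PatchRecord(img, mask, int(mask.any()), (0, 0))


def apply_dihedral(record: PatchRecord, quarter_turns: int, flip: bool) -> PatchRecord:
    """Rotate by 90° * quarter_turns then optionally flip horizontally."""
    img = np.rot90(record.image, quarter_turns, axes=(0, 1))
    mask = None if record.mask is None else np.rot90(record.mask, quarter_turns)
    if flip:
        img = img[:, ::-1]
        mask = None if mask is None else mask[:, ::-1]
    return PatchRecord(
        np.ascontiguousarray(img),
        None if mask is None else np.ascontiguousarray(mask),
        record.label,
        record.origin,
    )


def augment(record: PatchRecord, seed: int) -> PatchRecord:
    """One seeded training augmentation draw.

    A uniform draw over the 8 dihedral transforms (applied identically to
    image and mask), plus mild colour jitter on the image only (random
    per-channel gain in [0.9, 1.1] and shift in [-10, 10], applied with
    probability 1/2). The mask stays binary and the patch label unchanged.
    """
    rng = np.random.default_rng(seed)
    out = apply_dihedral(record, int(rng.integers(4)), bool(rng.integers(2)))
    if rng.random() < 0.5:
        gain = rng.uniform(0.9, 1.1, size=3)
        shift = rng.uniform(-10.0, 10.0, size=3)
        img = np.clip(out.image.astype(float) * gain + shift, 0, 255).astype(np.uint8)
        out = PatchRecord(img, out.mask, out.label, out.origin)
    return out


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as 8-bit PNG with 0 = background, 255 = foreground."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    """Read an 8-bit single-channel PNG mask; values >= 128 map to foreground."""
    img = Image.open(path)
    if img.mode != "L":
        raise ValueError(
            f"mask {path} must be 8-bit single-channel (mode 'L'), got {img.mode!r}"
        )
    arr = np.asarray(img)
    stray = ~np.isin(arr, (0, 255))
    if stray.any():
        warnings.warn(
            f"mask {path} contains {int(stray.sum())} values outside {{0, 255}}; "
            "applying the >=128 rule",
            stacklevel=2,
        )
    return (arr >= 128).astype(np.uint8)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as (H, W, 3) uint8 RGB."""
    return np.asarray(Image.open(path).convert("RGB"))


def write_manifest(records: list[tuple[str, str, int]], path) -> None:
    """Tab-separated manifest: image path, mask path (may be '-'), label."""
    with open(path, "w") as fh:
        for image_path, mask_path, label in records:
            fh.write(f"{image_path}\t{mask_path}\t{label}\n")


def read_manifest(path) -> list[tuple[str, str, int]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            image_path, mask_path, label = line.rstrip("\n").split("\t")
            rows.append((image_path, mask_path, int(label)))
    return rows


def synthesize_dataset(
    out_dir,
    n_train: int,
    n_val: int,
    n_test: int,
    params: SynthParams,
) -> dict[str, Path]:
    """Write a self-contained train/val/test tree of PNG patches + manifests.

    Sample indices are consecutive across splits, so the three splits are
    disjoint draws from one seeded stream. Returns the manifest paths.
    """
    out_dir = Path(out_dir)
    manifests = {}
    index = 0
    for split, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        split_dir = out_dir / split
        split_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for _ in range(count):
            rec = synthesize_sample(params, index)
            img_path = split_dir / f"patch_{index:05d}.png"
            mask_path = split_dir / f"patch_{index:05d}_mask.png"
            Image.fromarray(rec.image).save(img_path)
            write_mask(rec.mask, mask_path)
            rows.append((str(img_path), str(mask_path), rec.label))
            index += 1
        manifest = split_dir / "manifest.tsv"
        write_manifest(rows, manifest)
        manifests[split] = manifest
    return manifests
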