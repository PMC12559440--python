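"""Dataset loading, class-balancing augmentation planning, and pre-processing.

Datasets live on disk in the one-directory-per-class convention
(``root/<class_name>/*.jpg`` / ``*.png``).  Images are 8-bit RGB arrays;
pre-processing resizes everything to the 224x224 input expected by the
mobile CNN backbones and, at training time, rescales intensities to the
unit interval.

Class balance is restored by augmentation: each class is topped up to a
common target count with randomly perturbed copies (brightness, zoom,
rotation, horizontal flip) of its originals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "AugmentationConfig",
    "AugmentationPlan",
    "LabeledDataset",
    "augment_image",
    "load_image",
    "load_dataset",
    "plan_augmentation",
    "resize_to_input",
    "stratified_split",
    "validate_image",
]

INPUT_SIDE = 224  # backbone input side length in pixels


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a non-empty H x W x 3 array and return it."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {img.shape}")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("empty image")
    return img


@dataclass
class LabeledDataset:
    """Images with integer class labels and an ordered class-name list."""

    samples: list[tuple[np.ndarray, int]]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names must be unique")
        k = len(self.class_names)
        for _, label in self.samples:
            if not 0 <= label < k:
                raise ValueError(f"class index {label} outside [0, {k})")

    def __len__(self) -> int:
        return len(self.samples)

    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in self.class_names}
        for _, label in self.samples:
            counts[self.class_names[label]] += 1
        return counts

    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.samples], dtype=int)


@dataclass(frozen=True)
class AugmentationConfig:
    """Augmentation parameters.

    ``rescale_factor`` is the reciprocal intensity scale applied when images
    are fed to a model (1/255 maps 8-bit intensities onto [0, 1]); the
    geometric/photometric perturbations below operate on the 0-255 scale.
    Brightness and zoom factors are drawn uniformly from their ranges.
    """

    rescale_factor: float = 1.0 / 255.0
    brightness_range: tuple[float, float] = (0.8, 0.8)
    zoom_range: tuple[float, float] = (0.5, 0.5)
    rotation: float = 20.0  # max |degrees|
    horizontal_flip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rescale_factor <= 0:
            raise ValueError("rescale_factor must be positive")
        for lo, hi in (self.brightness_range, self.zoom_range):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")
        if self.rotation < 0:
            raise ValueError("rotation bound must be non-negative")


#: configuration that leaves every pixel untouched — handy for tests
IDENTITY_AUGMENTATION = AugmentationConfig(
    brightness_range=(1.0, 1.0),
    zoom_range=(1.0, 1.0),
    rotation=0.0,
    horizontal_flip=False,
)


@dataclass
class AugmentationPlan:
    """Per-class accounting of how many augmented copies are needed."""

    per_class: dict[str, tuple[int, int, int]]  # name -> (original, target, needed)

    def total_after(self) -> int:
        return sum(orig + need for orig, _, need in self.per_class.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": name, "original": orig, "target": tgt, "needed": need}
            for name, (orig, tgt, need) in self.per_class.items()
        ]
        return pd.DataFrame(rows, columns=["class", "original", "target", "needed"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AugmentationPlan":
        df = pd.read_csv(path)
        return cls(
            per_class={
                str(r["class"]): (int(r["original"]), int(r["target"]), int(r["needed"]))
                for _, r in df.iterrows()
            }
        )


def plan_augmentation(
    original_counts: Mapping[str, int], target_per_class: int
) -> AugmentationPlan:
    """Plan how many augmented images each class needs to reach the target.

    A class already at or above the target needs nothing; otherwise the
    deficit ``target - original`` is filled with augmented copies.
    """
    if target_per_class < 0:
        raise ValueError("target_per_class must be non-negative")
    per_class: dict[str, tuple[int, int, int]] = {}
    for name, count in original_counts.items():
        count = int(count)
        if count < 0:
            raise ValueError(f"negative count for class {name!r}")
        needed = max(0, target_per_class - count)
        per_class[name] = (count, target_per_class, needed)
    return AugmentationPlan(per_class=per_class)


def _zoom(img: np.ndarray, factor: float) -> np.ndarray:
    """Central crop-and-resize zoom.  factor < 1 zooms in, > 1 zooms out.

    Implemented as: crop the central ``factor`` fraction of the frame and
    resize back to the original shape (clamped so at least one pixel
    survives).
    """
    if factor == 1.0:
        return img
    h, w = img.shape[:2]
    ch = max(1, min(h, int(round(h * factor))))
    cw = max(1, min(w, int(round(w * factor))))
    top = (h - ch) // 2
    left = (w - cw) // 2
    crop = img[top : top + ch, left : left + cw]
    out = _sk_resize(crop.astype(float), (h, w), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out


def augment_image(
    img: np.ndarray, cfg: AugmentationConfig, draw_seed: int
) -> np.ndarray:
    """Apply one random augmentation draw to an 8-bit RGB image.

    The random draw is fully determined by ``(cfg.seed, draw_seed)``.
    Brightness is a multiplicative factor followed by clipping to [0, 255];
    zoom is a central crop-and-resize; rotation fills with nearest-border
    pixels.  Output dtype matches the uint8 input convention.
    """
    img = validate_image(img)
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, draw_seed & 0x7FFFFFFF])
    out = img.astype(float)

    brightness = rng.uniform(*cfg.brightness_range)
    zoom = rng.uniform(*cfg.zoom_range)
    angle = rng.uniform(-cfg.rotation, cfg.rotation) if cfg.rotation > 0 else 0.0
    flip = cfg.horizontal_flip and rng.random() < 0.5

    if brightness != 1.0:
        out = out * brightness
    if zoom != 1.0:
        out = _zoom(out, zoom)
    if angle != 0.0:
        out = _sk_rotate(out, angle, mode="edge", preserve_range=True, order=1)
    if flip:
        out = out[:, ::-1, :]

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def stratified_split(
    ds: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split into train/validation preserving per-class proportions.

    Per class, ``floor(train_fraction * n + 0.5)`` samples go to training and
    the remainder to validation; the shuffle within each class is driven by
    ``seed``, so the partition is reproducible, disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    counts = ds.class_counts()
    for name, n in counts.items():
        if n == 0:
            raise ValueError(f"class {name!r} has no samples")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {k: [] for k in range(len(ds.class_names))}
    for idx, (_, label) in enumerate(ds.samples):
        by_class[label].append(idx)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        rng.shuffle(idxs)
        n_train = int(math.floor(train_fraction * len(idxs) + 0.5))
        train_idx.extend(idxs[:n_train].tolist())
        val_idx.extend(idxs[n_train:].tolist())
    train = LabeledDataset(
        samples=[ds.samples[i] for i in train_idx], class_names=list(ds.class_names)
    )
    val = LabeledDataset(
        samples=[ds.samples[i] for i in val_idx], class_names=list(ds.class_names)
    )
    return train, val


def resize_to_input(
    img: np.ndarray, side: int = INPUT_SIDE, interpolation: str = "bilinear"
) -> np.ndarray:
    """Resize an RGB image to ``side x side`` (bilinear by default).

    ``interpolation="nearest"`` is exact on size-preserving calls and keeps
    constant images constant, which matters for pixel-identity tests.
    """
    img = validate_image(img)
    if side <= 0:
        raise ValueError("side must be positive")
    if img.shape[0] == side and img.shape[1] == side:
        return img.copy()
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    out = _sk_resize(img.astype(float), (side, side), order=order, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_dataset(root: str | Path, extensions: Sequence[str] = (".jpg", ".jpeg", ".png")) -> LabeledDataset:
    """Read a dir-per-class image dataset from disk.

    Class order is the sorted directory-name order; file order within a
    class is sorted, so loading is deterministic.
    """
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class directories under {root}")
    class_names = [p.name for p in class_dirs]
    samples: list[tuple[np.ndarray, int]] = []
    for label, cdir in enumerate(class_dirs):
        files = sorted(
            f for f in cdir.iterdir() if f.suffix.lower() in extensions
        )
        for f in files:
            samples.append((load_image(f), label))
    return LabeledDataset(samples=samples, class_names=class_names)


def rescale(img: np.ndarray, cfg: AugmentationConfig | None = None) -> np.ndarray:
    """Map 8-bit intensities to model scale (default: multiply by 1/255)."""
    factor = cfg.rescale_factor if cfg is not None else 1.0 / 255.0
    return np.asarray(img, dtype=float) * factor
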