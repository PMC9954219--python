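"""Image loading, preprocessing, deterministic augmentation and the
stratified five-fold split planner.

Preprocessing follows the classifier's input contract: images are resized
to 224x224 (bilinear), scaled to [0, 1], and z-score normalized per RGB
channel.  The default normalization statistics are the dataset-wide
channel means (0.2552, 0.4666, 0.8804) and standard deviations
(0.4116, 0.3645, 0.2597), applied in storage order R, G, B.

Augmentation is a fixed menu of exactly ten deterministic transforms
(rotations, magnifications, translations, a vertical flip), so each
original image yields ten training images: 1,320 originals expand to
13,200.  Augmentation is applied to the training split only; a
``paper_faithful`` switch exists to reproduce the 10x-of-total audit
counts, where augmented copies of every image (including eventual test
items) are produced, which leaks test content into training and is kept
only for bookkeeping comparisons.

The fold planner stratifies by class: per class the indices are shuffled
once (seeded) and cut into k contiguous chunks; chunk f is fold f's test
set, and ceil(val_frac x remainder) of the remaining indices become the
validation set.  On the class counts (300, 215, 215, 200, 200, 190) this
reproduces the reference split exactly: 264 test and 213 validation images
per fold, e.g. 35 validation images for the BT class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, resize as _sk_resize, rotate as _sk_rotate, warp

from .labels import CLASS_NAMES, ClassLabel

__all__ = [
    "LabeledImage",
    "NormalizationStats",
    "AugmentationPolicy",
    "Rotate",
    "Scale",
    "Translate",
    "VerticalFlip",
    "FoldPlan",
    "DataError",
    "StratificationError",
    "resize_image",
    "zscore_normalize",
    "default_augmentation_menu",
    "apply_augmentation",
    "build_fold_plan",
    "load_dataset",
    "DEFAULT_MEAN",
    "DEFAULT_STD",
]

# dataset-wide per-channel statistics (R, G, B) on the [0, 1] pixel scale
DEFAULT_MEAN = (0.2552, 0.4666, 0.8804)
DEFAULT_STD = (0.4116, 0.3645, 0.2597)


class DataError(ValueError):
    """Invalid image data or dataset layout."""


class StratificationError(DataError):
    """A class has too few samples for the requested fold count."""


@dataclass
class LabeledImage:
    """An RGB image with its diagnostic class.

    pixels: H x W x 3 float array with intensities in [0, 1] (before
    normalization); source_id identifies the originating file or generator
    call.
    """

    pixels: np.ndarray
    label: ClassLabel
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        self.label = ClassLabel(self.label)


@dataclass
class NormalizationStats:
    """Per-channel mean and standard deviation for z-score normalization."""

    mean: tuple[float, float, float] = DEFAULT_MEAN
    std: tuple[float, float, float] = DEFAULT_STD

    def __post_init__(self):
        if not all(s > 0 for s in self.std):
            raise DataError(f"std must be strictly positive, got {self.std}")

    @classmethod
    def from_images(cls, images) -> "NormalizationStats":
        """Channel statistics pooled over a collection of images."""
        stack = np.concatenate([im.pixels.reshape(-1, 3) for im in images], axis=0)
        std = stack.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(tuple(stack.mean(axis=0)), tuple(std))


def resize_image(img: LabeledImage, size: tuple[int, int] = (224, 224)) -> LabeledImage:
    """Bilinear resize to ``size`` (H, W), values clipped to [0, 1].

    Coordinate convention: pixel centres are aligned (the target pixel at
    index j samples the source at (j + 0.5) * scale - 0.5).  Upscaling is
    pure bilinear interpolation (no prefilter); downscaling applies the
    standard Gaussian anti-alias prefilter so sub-pixel structure (small
    tumour boundaries) averages instead of aliasing.
    """
    if img.pixels.shape[0] == 0 or img.pixels.shape[1] == 0:
        raise DataError("cannot resize a zero-dimension image")
    if img.pixels.shape[:2] == tuple(size):
        return LabeledImage(img.pixels.copy(), img.label, img.source_id)
    downscale = size[0] < img.pixels.shape[0] or size[1] < img.pixels.shape[1]
    out = _sk_resize(img.pixels, size, order=1, anti_aliasing=downscale,
                     preserve_range=True, mode="edge")
    return LabeledImage(np.clip(out, 0.0, 1.0), img.label, img.source_id)


def zscore_normalize(img: LabeledImage, stats: NormalizationStats | None = None) -> np.ndarray:
    """(pixel - mean_c) / std_c per channel; returns the normalized array."""
    stats = stats or NormalizationStats()
    mean = np.asarray(stats.mean, dtype=np.float64)
    std = np.asarray(stats.std, dtype=np.float64)
    return (img.pixels - mean) / std


# ---------------------------------------------------------------------------
# deterministic augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rotate:
    """Rotation about the image centre; positive angles are counterclockwise.

    Angle magnitudes are restricted to the 10-40 degree band used to move
    tumour foci around the field of view.
    """

    angle: float

    def __post_init__(self):
        if not 10.0 <= abs(self.angle) <= 40.0:
            raise DataError(f"rotation magnitude must lie in [10, 40] deg, got {self.angle}")

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        return _sk_rotate(pixels, self.angle, resize=False, order=1,
                          mode="constant", cval=0.0, preserve_range=True)


@dataclass(frozen=True)
class Scale:
    """Centre magnification by ``factor`` (1.10-1.12), crop back to size."""

    factor: float

    def __post_init__(self):
        if not 1.10 <= self.factor <= 1.12:
            raise DataError(f"scale factor must lie in [1.10, 1.12], got {self.factor}")

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        h, w = pixels.shape[:2]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        tf = AffineTransform(scale=(1 / self.factor, 1 / self.factor))
        shift = AffineTransform(translation=(-cx, -cy))
        unshift = AffineTransform(translation=(cx, cy))
        return warp(pixels, (shift + tf + unshift).inverse, order=1,
                    mode="constant", cval=0.0, preserve_range=True)


@dataclass(frozen=True)
class Translate:
    """Shift by (dx, dy) expressed as fractions of width / height.

    Positive dx moves content rightwards, positive dy downwards; exposed
    borders are filled with the background value 0.  Magnitudes follow the
    8-15% band of the augmentation recipe.
    """

    dx: float
    dy: float

    def __post_init__(self):
        for v in (self.dx, self.dy):
            if not 0.08 <= abs(v) <= 0.15:
                raise DataError(f"translation magnitude must lie in [0.08, 0.15], got {v}")

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        h, w = pixels.shape[:2]
        tx, ty = round(self.dx * w), round(self.dy * h)
        out = np.zeros_like(pixels)
        ys = slice(max(ty, 0), h + min(ty, 0))
        xs = slice(max(tx, 0), w + min(tx, 0))
        ys_src = slice(max(-ty, 0), h + min(-ty, 0))
        xs_src = slice(max(-tx, 0), w + min(-tx, 0))
        out[ys, xs] = pixels[ys_src, xs_src]
        return out


@dataclass(frozen=True)
class VerticalFlip:
    """Top-bottom mirror; an involution."""

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[::-1].copy()


@dataclass
class AugmentationPolicy:
    """Ordered list of deterministic transforms applied independently."""

    transforms: list

    def __len__(self):
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)


def default_augmentation_menu() -> AugmentationPolicy:
    """The fixed ten-transform menu: each original yields ten augmented
    images, expanding 1,320 originals into 13,200 training images."""
    return AugmentationPolicy([
        Rotate(+30.0),
        Rotate(-30.0),
        Rotate(+10.0),
        Rotate(-10.0),
        Scale(1.10),
        Scale(1.12),
        Translate(0.10, 0.10),
        Translate(0.08, 0.12),
        Translate(-0.10, -0.10),
        VerticalFlip(),
    ])


def paper_faithful_augmented_counts(class_counts: dict, policy: AugmentationPolicy | None = None) -> dict:
    """Audit bookkeeping: augmented counts as a multiple of the TOTAL class
    sizes (e.g. NT 300 -> 3000, 1,320 -> 13,200).

    Published augmented-count tables equal the menu length times the whole
    class, implying augmentation before splitting.  That recipe leaks
    augmented copies of test images into training, so this package never
    trains that way; the helper exists to reconcile bookkeeping against
    such tables.  Training-split augmentation goes through
    :func:`apply_augmentation` on the split instead.
    """
    n = len(policy or default_augmentation_menu())
    return {k: v * n for k, v in class_counts.items()}


def apply_augmentation(img: LabeledImage, policy: AugmentationPolicy | None = None) -> list[LabeledImage]:
    """One output image per transform; the label is preserved."""
    policy = policy or default_augmentation_menu()
    out = []
    for i, tf in enumerate(policy):
        pixels = np.clip(tf.apply(img.pixels), 0.0, 1.0)
        out.append(LabeledImage(pixels, img.label, f"{img.source_id}#aug{i}"))
    return out


# ---------------------------------------------------------------------------
# stratified fold planning
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Train/validation/test index assignment for k stratified folds."""

    k: int
    folds: list[dict[str, np.ndarray]]
    labels: np.ndarray

    def split_counts(self) -> dict[str, list[int]]:
        """Total train/validation/test sizes per fold."""
        return {
            part: [len(f[part]) for f in self.folds]
            for part in ("train", "validation", "test")
        }

    def class_counts(self, fold: int, part: str) -> dict[str, int]:
        idx = self.folds[fold][part]
        lab = self.labels[idx]
        return {name: int(np.sum(lab == ClassLabel[name])) for name in CLASS_NAMES}

    def to_json(self, path, paths: list[str] | None = None):
        """Serialize as fold -> split -> list of indices (or relative paths)."""
        def enc(idx):
            return [paths[i] for i in idx] if paths is not None else [int(i) for i in idx]

        doc = {
            "k": self.k,
            "labels": [ClassLabel(l).name for l in self.labels],
            "folds": [
                {part: enc(f[part]) for part in ("train", "validation", "test")}
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        doc = json.loads(Path(path).read_text())
        labels = np.array([ClassLabel[n] for n in doc["labels"]], dtype=int)
        folds = [
            {part: np.asarray(f[part], dtype=int) for part in ("train", "validation", "test")}
            for f in doc["folds"]
        ]
        return cls(doc["k"], folds, labels)


def build_fold_plan(labels, k: int = 5, val_frac: float = 0.2, seed=0) -> FoldPlan:
    """Stratified k-fold plan with a validation carve-out.

    Per class: seeded shuffle, contiguous k-chunks as test sets (remainder
    distributed round-robin to the first folds); per fold the non-test
    remainder contributes ceil(val_frac x remainder) validation indices and
    the rest trains.  Every sample is a test item in exactly one fold.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    labels = np.asarray([int(ClassLabel(l)) for l in np.asarray(labels).ravel()])
    n = labels.size
    rng = np.random.default_rng(seed)
    folds = [
        {"train": [], "validation": [], "test": []} for _ in range(k)
    ]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise StratificationError(
                f"class {ClassLabel(int(c)).name} has {idx.size} samples, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(idx.size, k)
        chunks, start = [], 0
        for f in range(k):
            size = base + (1 if f < rem else 0)
            chunks.append(idx[start : start + size])
            start += size
        for f in range(k):
            test = chunks[f]
            remainder = np.concatenate([chunks[j] for j in range(k) if j != f])
            n_val = math.ceil(val_frac * remainder.size)
            folds[f]["test"].append(test)
            folds[f]["validation"].append(remainder[:n_val])
            folds[f]["train"].append(remainder[n_val:])
    out = []
    for f in range(k):
        parts = {part: np.sort(np.concatenate(folds[f][part])) for part in folds[f]}
        union = np.sort(np.concatenate(list(parts.values())))
        assert union.size == n and np.array_equal(union, np.arange(n))
        out.append(parts)
    return FoldPlan(k, out, labels)


# ---------------------------------------------------------------------------
# folder I/O
# ---------------------------------------------------------------------------


def load_image(path, label: ClassLabel) -> LabeledImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return LabeledImage(arr, label, str(path))


def load_dataset(root) -> list[LabeledImage]:
    """Read PNG/JPEG images from one subfolder per class (NT/BT/MT/BBT/MMT/BMT)."""
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    images = []
    for name in CLASS_NAMES:
        sub = root / name
        if not sub.is_dir():
            raise DataError(f"missing class folder {sub}")
        for p in sorted(sub.iterdir()):
            if p.suffix.lower() in (".png", ".jpg", ".jpeg"):
                images.append(load_image(p, ClassLabel[name]))
    if not images:
        raise DataError(f"no images found under {root}")
    return images
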