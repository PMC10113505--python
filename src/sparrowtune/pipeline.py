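"""Image ingestion, preprocessing, augmentation and dataset partitioning.

Images are carried as float arrays in ``[0, 255]`` (H, W, 3) until one of
the four scaling methods is applied immediately before training.  The
pipeline stages are: resize to a common side length (bicubic), scale
per-image, optionally augment, equalize class sizes by augmenting
under-represented classes up to the largest class, and a stratified
train/validation/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, warp

from .codec import AugmentationConfig

__all__ = [
    "LabeledImageSet",
    "class_counts",
    "resize_image",
    "scale_image",
    "augment_image",
    "balanced_counts",
    "balance_by_augmentation",
    "split_dataset",
    "load_image_directory",
    "save_image_directory",
]

DEFAULT_IMAGE_SIZE = 128


@dataclass
class LabeledImageSet:
    """Parallel lists of images, labels and provenance.

    ``provenance[i]`` is ``"original"`` or ``"augmented"``; for augmented
    copies ``source_index[i]`` points at the original they were derived
    from (their *source group*), which the grouped split uses to keep
    copies in the same partition as their source.
    """

    images: list
    labels: list
    class_names: list
    provenance: list = field(default_factory=list)
    source_index: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must be parallel")
        for lab in self.labels:
            if lab not in self.class_names:
                raise ValueError(f"label {lab!r} not among class_names")
        if not self.provenance:
            self.provenance = ["original"] * len(self.images)
        if not self.source_index:
            self.source_index = list(range(len(self.images)))

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices: Sequence[int]) -> "LabeledImageSet":
        idx = list(indices)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            class_names=list(self.class_names),
            provenance=[self.provenance[i] for i in idx],
            source_index=[self.source_index[i] for i in idx],
        )

    def as_arrays(self) -> tuple:
        """Stack into (X, y) with y as integer class indices."""
        X = np.stack([np.asarray(im, dtype=float) for im in self.images])
        lut = {c: i for i, c in enumerate(self.class_names)}
        y = np.array([lut[lab] for lab in self.labels], dtype=int)
        return X, y


def class_counts(data: LabeledImageSet) -> dict:
    counts = {c: 0 for c in data.class_names}
    for lab in data.labels:
        counts[lab] += 1
    return counts


def resize_image(image: np.ndarray, size: int = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Bicubic resample to ``(size, size, 3)``.

    Grayscale input is replicated across three channels.  Channels are
    resampled in float precision (no 8-bit quantization), so constants are
    preserved exactly.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0 or arr.ndim not in (2, 3):
        raise ValueError("image must be a non-empty 2-D or 3-D array")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] != 3:
        raise ValueError("image must have 1 or 3 channels")
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr.copy()
    channels = []
    for c in range(3):
        im = Image.fromarray(arr[:, :, c].astype(np.float32), mode="F")
        channels.append(
            np.asarray(im.resize((size, size), resample=Image.BICUBIC), dtype=float)
        )
    return np.stack(channels, axis=2)


def scale_image(image: np.ndarray, method: str) -> np.ndarray:
    """Apply one of the four per-image intensity scalings.

    - ``normalize``: X / max(X)
    - ``standard``: (X - mean) / std
    - ``minmax``: (X - min) / (max - min)
    - ``maxabs``: X / max(|X|)

    Statistics are computed over the whole image.  A flat image (zero
    spread where the method needs spread) returns zeros with a warning.
    """
    arr = np.asarray(image, dtype=float)
    if method == "normalize":
        m = arr.max()
        if m == 0:
            warnings.warn("normalize: image max is 0; returning zeros")
            return np.zeros_like(arr)
        return arr / m
    if method == "standard":
        sd = arr.std()
        if sd == 0:
            warnings.warn("standard: image has zero variance; returning zeros")
            return np.zeros_like(arr)
        return (arr - arr.mean()) / sd
    if method == "minmax":
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            warnings.warn("minmax: image is constant; returning zeros")
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)
    if method == "maxabs":
        m = np.abs(arr).max()
        if m == 0:
            warnings.warn("maxabs: image is all zeros; returning zeros")
            return np.zeros_like(arr)
        return arr / m
    raise ValueError(f"unknown scaling method {method!r}")


def augment_image(
    image: np.ndarray,
    aug: AugmentationConfig,
    seed=None,
) -> np.ndarray:
    """One random augmentation draw applied to ``image``.

    Samples a rotation in ``[-r, +r]`` degrees, shifts/shear/zoom uniformly
    in their symmetric magnitude intervals, flips with probability 0.5
    where enabled, and a brightness multiplier uniform in
    ``brightness_range``; applies the combined centred affine map with
    reflect padding and bilinear interpolation, then flips, then
    brightness, clipping back to ``[0, 255]``.  Shape is preserved.
    ``seed`` may be an int or a Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.asarray(image, dtype=float)
    h, w = arr.shape[:2]
    # fixed draw order so determinism is independent of magnitudes
    angle = np.deg2rad(rng.uniform(-aug.rotation_deg, aug.rotation_deg))
    tx = rng.uniform(-aug.width_shift, aug.width_shift) * w
    ty = rng.uniform(-aug.height_shift, aug.height_shift) * h
    shear = rng.uniform(-aug.shear, aug.shear)
    zoom = 1.0 + rng.uniform(-aug.zoom, aug.zoom)
    do_hflip = aug.horizontal_flip and rng.uniform() < 0.5
    do_vflip = aug.vertical_flip and rng.uniform() < 0.5
    brightness = rng.uniform(*aug.brightness_range)

    out = arr
    if angle != 0.0 or tx != 0.0 or ty != 0.0 or shear != 0.0 or zoom != 1.0:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        center = AffineTransform(translation=(-cx, -cy))
        core = AffineTransform(
            scale=(zoom, zoom), rotation=angle, shear=shear
        )
        back = AffineTransform(translation=(cx + tx, cy + ty))
        tform = center + core + back
        out = warp(
            out,
            tform.inverse,
            mode="reflect",
            order=1,
            preserve_range=True,
        )
    if do_hflip:
        out = out[:, ::-1]
    if do_vflip:
        out = out[::-1, :]
    if brightness != 1.0:
        out = out * brightness
    return np.clip(np.ascontiguousarray(out, dtype=float), 0.0, 255.0)


def balanced_counts(counts: dict) -> dict:
    """Per-class sizes after the equalize-to-max rule (up-sampling only)."""
    for cls, n in counts.items():
        if n <= 0:
            raise ValueError(f"class {cls!r} has no images; cannot balance")
    target = max(counts.values())
    return {cls: target for cls in counts}


def balance_by_augmentation(
    data: LabeledImageSet,
    aug: AugmentationConfig,
    seed=None,
) -> LabeledImageSet:
    """Equalize class sizes by augmenting up to the largest class.

    Every class is raised to the size of the largest class by appending
    augmented copies of uniformly resampled members of that class; no
    image is ever removed or modified.  Copies are flagged ``"augmented"``
    with ``source_index`` pointing at their source.  An already balanced
    set is returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = class_counts(data)
    target = max(balanced_counts(counts).values())
    out = data.subset(range(len(data)))
    by_class = {c: [i for i, lab in enumerate(data.labels) if lab == c]
                for c in data.class_names}
    for cls in data.class_names:
        deficit = target - counts[cls]
        if deficit <= 0:
            continue
        picks = rng.choice(by_class[cls], size=deficit, replace=True)
        for src in picks:
            out.images.append(augment_image(data.images[src], aug, rng))
            out.labels.append(cls)
            out.provenance.append("augmented")
            # group with the source's own group so grouped splits hold
            out.source_index.append(data.source_index[src])
    return out


def _grouped_class_split(
    indices: list, groups: list, test_n: int, rng: np.random.Generator
) -> tuple:
    """Assign whole source-groups to test until ~test_n images are reached."""
    by_group: dict = {}
    for i, g in zip(indices, groups):
        by_group.setdefault(g, []).append(i)
    keys = list(by_group)
    rng.shuffle(keys)
    test, rest = [], []
    for g in keys:
        if len(test) < test_n:
            test.extend(by_group[g])
        else:
            rest.extend(by_group[g])
    return rest, test


def split_dataset(
    data: LabeledImageSet,
    train_ratio: float = 0.85,
    seed=None,
    validation_ratio: float = 0.15,
    group_by_source: bool = False,
) -> tuple:
    """Stratified shuffle split into (train, validation, test).

    ``train_ratio`` (default 0.85) is the training-plus-validation share;
    the rest is the test set.  ``validation_ratio`` (default 0.15) is then
    carved out of the training share.  Per class the test count is
    ``round((1 - train_ratio) * n_class)``, so the per-class test fraction
    is within one image of the global ratio.  With ``group_by_source``
    augmented copies always land in the same partition as their source
    image (whole groups are assigned, so exact per-class counts may drift
    by a group).
    """
    if not (0.0 < train_ratio < 1.0):
        raise ValueError("train_ratio must lie in (0, 1)")
    if not (0.0 <= validation_ratio < 1.0):
        raise ValueError("validation_ratio must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = class_counts(data)
    for cls, n in counts.items():
        if 0 < n < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 images")
    train_idx, val_idx, test_idx = [], [], []
    for cls in data.class_names:
        idx = [i for i, lab in enumerate(data.labels) if lab == cls]
        if not idx:
            continue
        n = len(idx)
        n_test = int(round((1.0 - train_ratio) * n))
        n_test = min(max(n_test, 1), n - 2)
        if group_by_source:
            groups = [data.source_index[i] for i in idx]
            rest, test = _grouped_class_split(idx, groups, n_test, rng)
            gr = [data.source_index[i] for i in rest]
            n_val = int(round(validation_ratio * len(rest)))
            if n_val > 0:
                train, val = _grouped_class_split(rest, gr, n_val, rng)
            else:
                train, val = rest, []
        else:
            perm = [idx[j] for j in rng.permutation(n)]
            test = perm[:n_test]
            rest = perm[n_test:]
            n_val = int(round(validation_ratio * len(rest)))
            val = rest[:n_val]
            train = rest[n_val:]
        train_idx.extend(train)
        val_idx.extend(val)
        test_idx.extend(test)
    return data.subset(train_idx), data.subset(val_idx), data.subset(test_idx)


# -- directory trees -------------------------------------------------------


def load_image_directory(root) -> LabeledImageSet:
    """Read a class-per-subdirectory tree of PNG/JPEG images."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    class_names = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not class_names:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels = [], []
    for cls in class_names:
        for f in sorted((root / cls).iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            with Image.open(f) as im:
                images.append(np.asarray(im.convert("RGB"), dtype=float))
            labels.append(cls)
    return LabeledImageSet(images=images, labels=labels, class_names=class_names)


def save_image_directory(data: LabeledImageSet, root) -> None:
    """Write a class-per-subdirectory PNG tree (intensities clipped to u8)."""
    root = Path(root)
    counters = {c: 0 for c in data.class_names}
    for img, lab, prov in zip(data.images, data.labels, data.provenance):
        d = root / lab
        d.mkdir(parents=True, exist_ok=True)
        tag = "aug" if prov == "augmented" else "img"
        arr = np.clip(np.asarray(img, dtype=float), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(d / f"{tag}_{counters[lab]:05d}.png")
        counters[lab] += 1
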