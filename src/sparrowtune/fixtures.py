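"""Seeded desk-scale test inputs: synthetic image sets and benchmark objectives.

The image generator renders each class as a distinct parametric texture —
an oriented sinusoidal grating mixed with a class-specific smoothed random
field whose granularity grades with the class index — so class
separability is controlled by a single ``signal_strength`` knob: at 0 all
class-conditional distributions coincide; at 1 with small noise a
nearest-centroid classifier separates the classes almost perfectly.  The
textures are deliberately synthetic stand-ins for the 4-class CT
(Cyst/Normal/Stone/Tumor) and 5-class histopathology grading problems;
they are not medically realistic, their only contract is controllable
separability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .pipeline import LabeledImageSet

__all__ = [
    "FixtureSpec",
    "generate_image_set",
    "benchmark_objective",
    "BenchmarkObjective",
    "FOUR_CLASS_NAMES",
    "FIVE_CLASS_NAMES",
]

FOUR_CLASS_NAMES = ("Cyst", "Normal", "Stone", "Tumor")
FIVE_CLASS_NAMES = ("Grade 0", "Grade 1", "Grade 2", "Grade 3", "Grade 4")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic labeled image set.

    ``per_class_counts`` maps class name to image count (imbalance is the
    point: it mirrors the skewed real class sizes).  ``signal_strength``
    in [0, 1] scales the class-distinguishing texture amplitude;
    ``noise_sd`` is the per-pixel Gaussian noise level on the 0-255 scale.
    The default 32-pixel side keeps test-time training cheap; the real
    pipeline operates at 128.
    """

    per_class_counts: dict
    image_size: int = 32
    signal_strength: float = 1.0
    noise_sd: float = 8.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.per_class_counts:
            raise ValueError("per_class_counts must be non-empty")
        for cls, n in self.per_class_counts.items():
            if n <= 0:
                raise ValueError(f"class {cls!r} must have a positive count")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")

    @property
    def n_classes(self) -> int:
        return len(self.per_class_counts)

    @classmethod
    def four_class(cls, counts=(3709, 5077, 1377, 2283), **kw) -> "FixtureSpec":
        """Spec shaped like the imbalanced 4-class CT problem."""
        return cls(per_class_counts=dict(zip(FOUR_CLASS_NAMES, counts)), **kw)

    @classmethod
    def five_class(cls, counts=(45, 45, 60, 67, 60), **kw) -> "FixtureSpec":
        """Spec shaped like the imbalanced 5-class grading problem."""
        return cls(per_class_counts=dict(zip(FIVE_CLASS_NAMES, counts)), **kw)


def _class_texture(k: int, n_classes: int, size: int, seed: int) -> np.ndarray:
    """Deterministic unit-variance texture for class ``k``."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    theta = np.pi * k / n_classes
    freq = 3.0 + 2.0 * k
    grating = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
    rng = np.random.default_rng((seed, k))
    blob_scale = size / (6.0 + 2.0 * k)  # granularity grades with class index
    blobs = gaussian_filter(rng.standard_normal((size, size)), blob_scale / 4.0)
    tex = grating + 1.5 * blobs / (blobs.std() + 1e-12)
    return tex / tex.std()


def generate_image_set(spec: FixtureSpec) -> LabeledImageSet:
    """Render the image set described by ``spec``; deterministic per seed.

    Each image is ``base 128 + signal_strength * 55 * texture_k + noise``
    clipped to [0, 255] and replicated to three channels.
    """
    rng = np.random.default_rng(spec.seed)
    class_names = list(spec.per_class_counts)
    texture_seed = spec.seed if spec.seed is not None else 0
    textures = {
        cls: _class_texture(k, spec.n_classes, spec.image_size, texture_seed)
        for k, cls in enumerate(class_names)
    }
    images, labels = [], []
    for cls in class_names:
        tex = textures[cls]
        for _ in range(spec.per_class_counts[cls]):
            noise = rng.standard_normal((spec.image_size, spec.image_size))
            gray = 128.0 + spec.signal_strength * 55.0 * tex + spec.noise_sd * noise
            gray = np.clip(gray, 0.0, 255.0)
            images.append(np.repeat(gray[:, :, None], 3, axis=2))
            labels.append(cls)
    return LabeledImageSet(images=images, labels=labels, class_names=class_names)


@dataclass(frozen=True)
class BenchmarkObjective:
    """A deterministic objective on [0, 1]^D with a known optimum."""

    name: str
    dimension: int
    fn: Callable = field(repr=False)
    optimum_location: np.ndarray = field(repr=False)
    optimum_value: float = 0.0
    maximize: bool = False

    def __call__(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(f"expected a vector of length {self.dimension}")
        return float(self.fn(x))


def benchmark_objective(
    name: str, dimension: int, target: Optional[np.ndarray] = None
) -> BenchmarkObjective:
    """Standard optimizer-validation objectives on the unit cube.

    - ``sphere``: sum of squared deviations from the centre (minimize,
      optimum 0 at 0.5 everywhere).
    - ``rastrigin``: the multimodal Rastrigin function with each
      coordinate mapped to [-5.12, 5.12] (minimize, optimum 0 at centre).
    - ``target-vector``: ``1 - mean((x - v)^2)`` for a target ``v``
      (maximize, optimum 1 at ``v``); ``v`` defaults to a fixed
      deterministic vector.
    """
    if dimension < 1:
        raise ValueError("dimension must be positive")
    center = np.full(dimension, 0.5)
    if name == "sphere":
        return BenchmarkObjective(
            name=name,
            dimension=dimension,
            fn=lambda x: float(((x - 0.5) ** 2).sum()),
            optimum_location=center,
            optimum_value=0.0,
            maximize=False,
        )
    if name == "rastrigin":

        def rastrigin(x):
            z = (x - 0.5) * 2.0 * 5.12
            return float(10.0 * len(z) + (z**2 - 10.0 * np.cos(2 * np.pi * z)).sum())

        return BenchmarkObjective(
            name=name,
            dimension=dimension,
            fn=rastrigin,
            optimum_location=center,
            optimum_value=0.0,
            maximize=False,
        )
    if name == "target-vector":
        if target is None:
            target = np.random.default_rng(12345).uniform(0.2, 0.8, size=dimension)
        target = np.asarray(target, dtype=float)
        if target.shape != (dimension,):
            raise ValueError("target must have length `dimension`")
        return BenchmarkObjective(
            name=name,
            dimension=dimension,
            fn=lambda x, v=target: float(1.0 - ((x - v) ** 2).mean()),
            optimum_location=target.copy(),
            optimum_value=1.0,
            maximize=True,
        )
    raise ValueError(
        "unknown objective name; choose from 'sphere', 'rastrigin', 'target-vector'"
    )
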