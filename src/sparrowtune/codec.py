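"""Bidirectional mapping between unit-interval vectors and hyperparameters.

The optimizer works on points of ``[0, 1]^D``; each coordinate encodes one
training hyperparameter.  The full space has D = 15 dimensions (positions
1-7: loss, batch size, dropout, fine-tune learn ratio, optimizer, scaler,
augmentation flag; positions 8-15: the augmentation magnitudes).  When the
augmentation flag decodes to False the trailing eight coordinates are
carried but ignored, so the optimizer always sees a fixed-dimension space;
the reduced D = 7 space is the projection onto the first seven coordinates.

Discrete dimensions with ``n`` choices map a coordinate ``v`` to index
``floor(v * n)`` (clamped to ``n - 1`` at ``v = 1``): e.g. ``v = 0.85``
against the 12-value batch-size grid ``4, 8, ..., 48`` selects index 11,
i.e. batch size 44.  Continuous dimensions interpolate linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "DimensionSpec",
    "SearchSpace",
    "TrainingConfig",
    "AugmentationConfig",
    "map_element",
    "decode",
    "describe",
    "parse_record",
    "LOSSES",
    "OPTIMIZERS",
    "SCALERS",
]

LOSSES = (
    "categorical_crossentropy",
    "categorical_hinge",
    "kl_divergence",
    "poisson",
    "squared_hinge",
    "hinge",
)

OPTIMIZERS = (
    "adam",
    "nadam",
    "adagrad",
    "adadelta",
    "adamax",
    "rmsprop",
    "sgd",
    "ftrl",
    "sgd_nesterov",
    "rmsprop_centered",
    "adam_amsgrad",
)

SCALERS = ("normalize", "standard", "minmax", "maxabs")

#: Half-width of the decoded brightness interval around its centre.  One
#: coordinate encodes a centre c in [0.5, 2.0]; the emitted range is
#: [max(0.5, c - w), min(2.0, c + w)].
BRIGHTNESS_HALF_WIDTH = 0.3


@dataclass(frozen=True)
class DimensionSpec:
    """One hyperparameter dimension of the search space."""

    name: str
    kind: str  # categorical | integer-range | real-range | boolean | real-pair
    choices: Optional[tuple] = None
    low: Optional[float] = None
    high: Optional[float] = None
    step: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in (
            "categorical",
            "integer-range",
            "real-range",
            "boolean",
            "real-pair",
        ):
            raise ValueError(f"unknown dimension kind: {self.kind!r}")
        if self.kind == "categorical" and not self.choices:
            raise ValueError(f"{self.name}: categorical choices must be non-empty")
        if self.kind in ("integer-range", "real-range", "real-pair"):
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"{self.name}: requires low < high")
            if self.kind == "integer-range" and (self.step is None or self.step <= 0):
                raise ValueError(f"{self.name}: integer-range requires step > 0")

    @property
    def n_choices(self) -> Optional[int]:
        """Number of discrete options (categorical/integer-range/boolean)."""
        if self.kind == "categorical":
            return len(self.choices)
        if self.kind == "boolean":
            return 2
        if self.kind == "integer-range":
            return int(round((self.high - self.low) / self.step)) + 1
        return None


def default_search_space() -> "SearchSpace":
    """The 15-dimension space with the study's hyperparameter grid."""
    dims = [
        DimensionSpec("loss", "categorical", choices=LOSSES),
        DimensionSpec("batch_size", "integer-range", low=4, high=48, step=4),
        DimensionSpec("dropout", "real-range", low=0.0, high=0.6),
        DimensionSpec("tl_learn_ratio", "integer-range", low=1, high=100, step=1),
        DimensionSpec("optimizer", "categorical", choices=OPTIMIZERS),
        DimensionSpec("scaler", "categorical", choices=SCALERS),
        DimensionSpec("augment", "boolean"),
        DimensionSpec("rotation_deg", "integer-range", low=0, high=45, step=1),
        DimensionSpec("width_shift", "real-range", low=0.0, high=0.25),
        DimensionSpec("height_shift", "real-range", low=0.0, high=0.25),
        DimensionSpec("shear", "real-range", low=0.0, high=0.25),
        DimensionSpec("zoom", "real-range", low=0.0, high=0.25),
        DimensionSpec("horizontal_flip", "boolean"),
        DimensionSpec("vertical_flip", "boolean"),
        DimensionSpec("brightness_center", "real-range", low=0.5, high=2.0),
    ]
    return SearchSpace(dimensions=tuple(dims))


@dataclass(frozen=True)
class SearchSpace:
    """Ordered hyperparameter dimensions; full space D=15, reduced D=7.

    ``reduced=True`` restricts to the first seven dimensions (no
    augmentation coordinates), the variant used when augmentation is ruled
    out up front.
    """

    dimensions: tuple
    reduced: bool = False

    def __post_init__(self) -> None:
        if len(self.dimensions) != 15:
            raise ValueError("the full search space has exactly 15 dimensions")

    @property
    def active_dimensions(self) -> tuple:
        return self.dimensions[:7] if self.reduced else self.dimensions

    @property
    def dimension(self) -> int:
        return 7 if self.reduced else 15

    def to_dict(self) -> dict:
        return {
            "reduced": self.reduced,
            "dimensions": [
                {
                    "name": d.name,
                    "kind": d.kind,
                    "choices": list(d.choices) if d.choices else None,
                    "low": d.low,
                    "high": d.high,
                    "step": d.step,
                }
                for d in self.dimensions
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SearchSpace":
        dims = tuple(
            DimensionSpec(
                name=d["name"],
                kind=d["kind"],
                choices=tuple(d["choices"]) if d.get("choices") else None,
                low=d.get("low"),
                high=d.get("high"),
                step=d.get("step"),
            )
            for d in payload["dimensions"]
        )
        return cls(dimensions=dims, reduced=payload.get("reduced", False))


@dataclass(frozen=True)
class AugmentationConfig:
    """Random-augmentation magnitudes (rotation in degrees, shifts/shear/zoom
    as fractions, brightness as a multiplicative range)."""

    rotation_deg: int = 0
    width_shift: float = 0.0
    height_shift: float = 0.0
    shear: float = 0.0
    zoom: float = 0.0
    horizontal_flip: bool = False
    vertical_flip: bool = False
    brightness_range: tuple = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not (0 <= self.rotation_deg <= 45):
            raise ValueError("rotation_deg must lie in [0, 45]")
        for name in ("width_shift", "height_shift", "shear", "zoom"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.25):
                raise ValueError(f"{name} must lie in [0, 0.25]")
        lo, hi = self.brightness_range
        if not (0.5 <= lo <= hi <= 2.0):
            raise ValueError("brightness_range must be ordered within [0.5, 2.0]")

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.width_shift == 0.0
            and self.height_shift == 0.0
            and self.shear == 0.0
            and self.zoom == 0.0
            and not self.horizontal_flip
            and not self.vertical_flip
            and self.brightness_range == (1.0, 1.0)
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Concrete, decoded training hyperparameters."""

    loss: str = "categorical_crossentropy"
    batch_size: int = 32
    dropout: float = 0.0
    tl_learn_ratio: int = 100
    optimizer: str = "adam"
    scaler: str = "normalize"
    augment: bool = False
    augmentation: Optional[AugmentationConfig] = None

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {LOSSES}")
        if self.batch_size not in range(4, 49, 4):
            raise ValueError("batch_size must lie on the 4..48 step-4 grid")
        if not (0.0 <= self.dropout <= 0.6):
            raise ValueError("dropout must lie in [0, 0.6]")
        if not (0 <= self.tl_learn_ratio <= 100):
            raise ValueError("tl_learn_ratio must lie in [0, 100]")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {OPTIMIZERS}"
            )
        if self.scaler not in SCALERS:
            raise ValueError(f"unknown scaler {self.scaler!r}; choose from {SCALERS}")
        if self.augment and self.augmentation is None:
            raise ValueError("augment=True requires an AugmentationConfig")


def map_element(value: float, spec: DimensionSpec):
    """Decode one coordinate ``value`` in [0, 1] under ``spec``.

    Discrete kinds use the floor-index rule ``floor(value * n_choices)``
    (clamped at ``value = 1``); continuous kinds interpolate
    ``low + value * (high - low)``; booleans threshold at 0.5.
    """
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"element value {value} outside [0, 1]")
    if spec.kind == "categorical":
        idx = min(int(math.floor(value * len(spec.choices))), len(spec.choices) - 1)
        return spec.choices[idx]
    if spec.kind == "boolean":
        return value >= 0.5
    if spec.kind == "integer-range":
        n = spec.n_choices
        idx = min(int(math.floor(value * n)), n - 1)
        return int(round(spec.low + idx * spec.step))
    if spec.kind == "real-range":
        return float(spec.low + value * (spec.high - spec.low))
    raise ValueError(f"cannot map kind {spec.kind!r}")  # pragma: no cover


def decode(solution: Union[np.ndarray, Sequence[float]], space: SearchSpace) -> TrainingConfig:
    """Decode a full solution vector into a :class:`TrainingConfig`.

    Accepts length-15 vectors (full space) or length-7 vectors (reduced
    space, augmentation forced off).  The augmentation block (positions
    8-15) is decoded only when the flag at position 7 decodes to True.
    """
    values = np.asarray(solution, dtype=float).ravel()
    expected = space.dimension
    if values.shape[0] != expected:
        raise ValueError(
            f"solution has {values.shape[0]} elements; search space expects {expected}"
        )
    if np.any(values < 0.0) or np.any(values > 1.0):
        raise ValueError("solution elements must lie in [0, 1]")
    dims = space.dimensions
    loss = map_element(values[0], dims[0])
    batch_size = map_element(values[1], dims[1])
    dropout = map_element(values[2], dims[2])
    tl_ratio = map_element(values[3], dims[3])
    optimizer = map_element(values[4], dims[4])
    scaler = map_element(values[5], dims[5])
    augment = False if space.reduced else bool(map_element(values[6], dims[6]))
    augmentation = None
    if augment:
        center = map_element(values[14], dims[14])
        brightness = (
            max(0.5, center - BRIGHTNESS_HALF_WIDTH),
            min(2.0, center + BRIGHTNESS_HALF_WIDTH),
        )
        augmentation = AugmentationConfig(
            rotation_deg=map_element(values[7], dims[7]),
            width_shift=map_element(values[8], dims[8]),
            height_shift=map_element(values[9], dims[9]),
            shear=map_element(values[10], dims[10]),
            zoom=map_element(values[11], dims[11]),
            horizontal_flip=map_element(values[12], dims[12]),
            vertical_flip=map_element(values[13], dims[13]),
            brightness_range=brightness,
        )
    return TrainingConfig(
        loss=loss,
        batch_size=batch_size,
        dropout=dropout,
        tl_learn_ratio=tl_ratio,
        optimizer=optimizer,
        scaler=scaler,
        augment=augment,
        augmentation=augmentation,
    )


_NA = "N/A"

_RECORD_FIELDS = (
    "Loss",
    "Batch size",
    "Dropout",
    "TL learn ratio",
    "Optimizer",
    "Scaler",
    "Apply augmentation",
    "Rotation range",
    "Width shift range",
    "Height shift range",
    "Shear range",
    "Zoom range",
    "Horizontal flip",
    "Vertical flip",
    "Brightness range",
)


def describe(config: TrainingConfig) -> dict:
    """Flatten a config into the one-row logging record layout."""
    rec = {
        "Loss": config.loss,
        "Batch size": config.batch_size,
        "Dropout": round(config.dropout, 4),
        "TL learn ratio": config.tl_learn_ratio,
        "Optimizer": config.optimizer,
        "Scaler": config.scaler,
        "Apply augmentation": "Yes" if config.augment else "No",
    }
    if config.augment:
        aug = config.augmentation
        rec.update(
            {
                "Rotation range": aug.rotation_deg,
                "Width shift range": round(aug.width_shift, 4),
                "Height shift range": round(aug.height_shift, 4),
                "Shear range": round(aug.shear, 4),
                "Zoom range": round(aug.zoom, 4),
                "Horizontal flip": "Yes" if aug.horizontal_flip else "No",
                "Vertical flip": "Yes" if aug.vertical_flip else "No",
                "Brightness range": (
                    f"{aug.brightness_range[0]:.2f}-{aug.brightness_range[1]:.2f}"
                ),
            }
        )
    else:
        rec.update({k: _NA for k in _RECORD_FIELDS[7:]})
    return rec


_LOSS_ALIASES = {
    "categorical crossentropy": "categorical_crossentropy",
    "categorical hinge": "categorical_hinge",
    "kldivergence": "kl_divergence",
    "kl divergence": "kl_divergence",
    "poisson": "poisson",
    "squared hinge": "squared_hinge",
    "hinge": "hinge",
}

_OPTIMIZER_ALIASES = {
    "adam": "adam",
    "nadam": "nadam",
    "adagrad": "adagrad",
    "adadelta": "adadelta",
    "adamax": "adamax",
    "rmsprop": "rmsprop",
    "sgd": "sgd",
    "ftrl": "ftrl",
    "sgd nesterov": "sgd_nesterov",
    "rmsprop centered": "rmsprop_centered",
    "adam amsgrad": "adam_amsgrad",
}

_SCALER_ALIASES = {
    "normalize": "normalize",
    "normalization": "normalize",
    "standard": "standard",
    "standardization": "standard",
    "minmax": "minmax",
    "min max": "minmax",
    "maxabs": "maxabs",
    "max abs": "maxabs",
}


def _canon(value: str, aliases: dict, what: str) -> str:
    key = str(value).strip().lower().replace("-", " ").replace("_", " ")
    key2 = key.replace(" ", "_")
    if key in aliases:
        return aliases[key]
    if key2 in aliases.values():
        return key2
    raise ValueError(f"cannot interpret {what} {value!r}")


def parse_record(record: dict) -> TrainingConfig:
    """Inverse of :func:`describe`: build a config from a flat record.

    Accepts the human spellings used in published result tables (e.g.
    ``"SGD Nesterov"``, ``"MinMax"``) as well as the canonical identifiers.
    """
    augment = str(record.get("Apply augmentation", "No")).strip().lower() in (
        "yes",
        "true",
        "1",
    )
    augmentation = None
    if augment:
        br = str(record["Brightness range"]).replace("–", "-")
        lo, hi = (float(x) for x in br.split("-"))
        augmentation = AugmentationConfig(
            rotation_deg=int(record["Rotation range"]),
            width_shift=float(record["Width shift range"]),
            height_shift=float(record["Height shift range"]),
            shear=float(record["Shear range"]),
            zoom=float(record["Zoom range"]),
            horizontal_flip=str(record["Horizontal flip"]).strip().lower()
            in ("yes", "true", "1"),
            vertical_flip=str(record["Vertical flip"]).strip().lower()
            in ("yes", "true", "1"),
            brightness_range=(lo, hi),
        )
    return TrainingConfig(
        loss=_canon(record["Loss"], _LOSS_ALIASES, "loss"),
        batch_size=int(record["Batch size"]),
        dropout=float(record["Dropout"]),
        tl_learn_ratio=int(record["TL learn ratio"]),
        optimizer=_canon(record["Optimizer"], _OPTIMIZER_ALIASES, "optimizer"),
        scaler=_canon(record["Scaler"], _SCALER_ALIASES, "scaler"),
        augment=augment,
        augmentation=augmentation,
    )
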