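"""Classifier construction, fitness evaluation and the two-stage cascade.

The trainable unit is :class:`TransferImageClassifier`, a scikit-learn
style estimator wrapping a small convolutional network: a backbone of
conv/pool blocks, a dropout layer over the pooled features, and a softmax
output.  The decoded hyperparameters select the loss, optimizer, batch
size, dropout rate, per-image scaler, augmentation policy and the
fine-tune ratio (the percentage of backbone blocks, counted from the
output end, left trainable).

Backbones are registered by name.  ``surrogate-tiny`` (three conv blocks)
is the tested reference that runs on CPU in seconds; the familiar
ImageNet-era names construct scaled-down, randomly initialised
architecture sketches of matching relative depth — pretrained weights are
not bundled, so requesting ``pretrained_init`` only warns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .codec import TrainingConfig
from .metrics import MetricReport, full_report
from .nn import Conv2D, Dense, Dropout, GlobalAvgPool, MaxPool2, NeuralNetwork, ReLU
from .nn.network import DivergenceError
from .pipeline import LabeledImageSet, augment_image, scale_image

__all__ = [
    "BackboneSpec",
    "BACKBONE_WIDTHS",
    "FitnessResult",
    "TransferImageClassifier",
    "build_model",
    "evaluate_fitness",
    "cascade_predict",
]

#: Conv-block widths per backbone name.  Depth loosely tracks the relative
#: depth of the namesake architectures; widths are kept small so every
#: backbone is constructible and trainable offline on one CPU.
BACKBONE_WIDTHS = {
    "surrogate-tiny": (16, 32, 64),
    "VGG16": (8, 16, 32, 32, 64),
    "VGG19": (8, 16, 32, 32, 64, 64),
    "Xception": (16, 32, 64, 64),
    "DenseNet201": (8, 16, 32, 64, 64, 64),
    "MobileNet": (8, 16, 32, 64),
    "MobileNetV2": (8, 16, 32, 32),
    "MobileNetV3Large": (16, 32, 64, 64),
    "NASNetMobile": (8, 16, 32, 64, 64),
}


@dataclass(frozen=True)
class BackboneSpec:
    """A backbone choice; ``surrogate-tiny`` is always constructible."""

    name: str = "surrogate-tiny"
    pretrained_init: bool = False

    def __post_init__(self) -> None:
        resolve_backbone_name(self.name)


def resolve_backbone_name(name: str) -> str:
    lut = {k.lower(): k for k in BACKBONE_WIDTHS}
    try:
        return lut[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; valid names: {sorted(BACKBONE_WIDTHS)}"
        ) from None


@dataclass
class FitnessResult:
    """Outcome of one fitness evaluation."""

    score: float
    metric_report: Optional[MetricReport]
    config: TrainingConfig
    epochs_run: int
    diverged: bool = False
    evaluation_mode: str = "holdout"


class TransferImageClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional image classifier with tunable training hyperparameters.

    Parameters mirror the search space: ``loss``, ``batch_size``,
    ``dropout``, ``tl_learn_ratio`` (percent of backbone blocks left
    trainable, from the output end), ``optimizer``, ``scaler`` (per-image
    intensity scaling applied inside fit/predict), ``augment`` plus an
    :class:`~sparrowtune.codec.AugmentationConfig`, and ``epochs``.

    ``X`` is an ``(n, H, W, 3)`` array of raw intensities in [0, 255];
    ``y`` may be integers or class-name strings.

    Examples
    --------
    >>> from sparrowtune.fixtures import FixtureSpec, generate_image_set
    >>> data = generate_image_set(FixtureSpec({"a": 10, "b": 10}, seed=0))
    >>> X, y = data.as_arrays()
    >>> clf = TransferImageClassifier(epochs=2, random_state=0).fit(X, y)
    >>> clf.predict(X).shape
    (20,)
    """

    def __init__(
        self,
        backbone: str = "surrogate-tiny",
        loss: str = "categorical_crossentropy",
        batch_size: int = 32,
        dropout: float = 0.0,
        tl_learn_ratio: int = 100,
        optimizer: str = "adam",
        scaler: str = "normalize",
        augment: bool = False,
        augmentation=None,
        epochs: int = 5,
        random_state=None,
    ):
        self.backbone = backbone
        self.loss = loss
        self.batch_size = batch_size
        self.dropout = dropout
        self.tl_learn_ratio = tl_learn_ratio
        self.optimizer = optimizer
        self.scaler = scaler
        self.augment = augment
        self.augmentation = augmentation
        self.epochs = epochs
        self.random_state = random_state

    @classmethod
    def from_config(
        cls,
        config: TrainingConfig,
        backbone: str = "surrogate-tiny",
        epochs: int = 5,
        random_state=None,
    ) -> "TransferImageClassifier":
        return cls(
            backbone=backbone,
            loss=config.loss,
            batch_size=config.batch_size,
            dropout=config.dropout,
            tl_learn_ratio=config.tl_learn_ratio,
            optimizer=config.optimizer,
            scaler=config.scaler,
            augment=config.augment,
            augmentation=config.augmentation,
            epochs=epochs,
            random_state=random_state,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must be an (n, H, W, 3) image array")
        return X

    def _prep(self, X: np.ndarray) -> np.ndarray:
        return np.stack([scale_image(im, self.scaler) for im in X])

    def fit(self, X, y) -> "TransferImageClassifier":
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y must be parallel")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        self.model_ = build_model(
            self.backbone,
            self._config(),
            n_classes=len(self.classes_),
            rng=rng,
        )
        if self.augment and self.augmentation is not None:

            def augment_fn(batch, batch_rng):
                out = np.stack(
                    [augment_image(im, self.augmentation, batch_rng) for im in batch]
                )
                return self._prep(out)

            X_in, fn = X, augment_fn
        else:
            X_in, fn = self._prep(X), None
        self.diverged_ = False
        self.epochs_run_ = 0
        try:
            self.model_.fit(
                X_in,
                y_idx,
                epochs=self.epochs,
                batch_size=self.batch_size,
                augment_fn=fn,
            )
            self.epochs_run_ = int(self.epochs)
        except DivergenceError:
            self.diverged_ = True
            self.epochs_run_ = len(self.model_.history)
        return self

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            loss=self.loss,
            batch_size=self.batch_size,
            dropout=self.dropout,
            tl_learn_ratio=self.tl_learn_ratio,
            optimizer=self.optimizer,
            scaler=self.scaler,
            augment=self.augment,
            augmentation=self.augmentation,
        )

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        return self.model_.predict_proba(self._prep(self._validate_X(X)))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    @property
    def n_trainable_params_(self) -> int:
        return self.model_.n_trainable_params


def build_model(
    backbone: Union[str, BackboneSpec],
    config: TrainingConfig,
    n_classes: int,
    rng=None,
) -> NeuralNetwork:
    """Assemble backbone + dropout head + softmax output.

    The fine-tune ratio freezes the bottom ``(100 - tl_learn_ratio)%`` of
    backbone conv blocks (``ceil(ratio / 100 * n_blocks)`` blocks stay
    trainable, counted from the output end; ratio 0 freezes the whole
    backbone).  The head is always trainable.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if isinstance(backbone, BackboneSpec):
        if backbone.pretrained_init:
            warnings.warn(
                "pretrained weights are not bundled; using random initialisation"
            )
        name = resolve_backbone_name(backbone.name)
    else:
        name = resolve_backbone_name(backbone)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    widths = BACKBONE_WIDTHS[name]
    n_blocks = len(widths)
    n_trainable = (
        0
        if config.tl_learn_ratio <= 0
        else min(n_blocks, math.ceil(config.tl_learn_ratio / 100.0 * n_blocks))
    )
    layers = []
    in_ch = 3
    for bi, width in enumerate(widths):
        conv = Conv2D(in_ch, width, rng)
        trainable = bi >= n_blocks - n_trainable
        conv.trainable = trainable
        layers.extend([conv, ReLU(), MaxPool2()])
        in_ch = width
    layers.append(GlobalAvgPool())
    layers.append(Dropout(config.dropout))
    layers.append(Dense(in_ch, n_classes, rng))
    return NeuralNetwork(
        layers, loss=config.loss, optimizer=config.optimizer, seed=rng
    )


def _as_xy(data) -> tuple:
    if isinstance(data, LabeledImageSet):
        return data.as_arrays()
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y)


def evaluate_fitness(
    backbone,
    config: TrainingConfig,
    train,
    validation,
    evaluation_set=None,
    epochs: int = 5,
    seed=None,
    evaluation_mode: str = "holdout",
) -> FitnessResult:
    """Train a classifier under ``config`` and score it.

    ``evaluation_mode`` selects the scored set: ``"holdout"`` (default)
    scores the validation set only, while ``"whole-dataset"`` scores the
    union of train and validation (an optimistic convention that mixes
    training data into the fitness; provided for comparability, and always
    recorded on the result).  An explicit ``evaluation_set`` overrides
    both.  Training failures (non-finite loss) yield score 0 with the
    ``diverged`` flag instead of raising, so an optimizer exploring bad
    loss/optimizer pairings can continue.
    """
    if epochs < 1:
        raise ValueError("epochs must be at least 1")
    Xtr, ytr = _as_xy(train)
    Xval, yval = _as_xy(validation)
    clf = TransferImageClassifier.from_config(
        config, backbone=backbone, epochs=epochs, random_state=seed
    )
    clf.fit(Xtr, ytr)
    if evaluation_set is not None:
        Xev, yev = _as_xy(evaluation_set)
        evaluation_mode = "explicit"
    elif evaluation_mode == "whole-dataset":
        Xev = np.concatenate([Xtr, Xval])
        yev = np.concatenate([ytr, yval])
    elif evaluation_mode == "holdout":
        Xev, yev = Xval, yval
    else:
        raise ValueError("evaluation_mode must be 'holdout' or 'whole-dataset'")
    if clf.diverged_:
        return FitnessResult(
            score=0.0,
            metric_report=None,
            config=config,
            epochs_run=clf.epochs_run_,
            diverged=True,
            evaluation_mode=evaluation_mode,
        )
    probs = clf.predict_proba(Xev)
    lut = {c: i for i, c in enumerate(clf.classes_)}
    try:
        y_idx = np.array([lut[v] for v in yev], dtype=int)
    except KeyError as exc:
        raise ValueError(
            "evaluation set contains a label unseen in training; "
            "use a stratified split"
        ) from exc
    report = full_report(y_idx, probs, mode="argmax")
    return FitnessResult(
        score=float(report.accuracy),
        metric_report=report,
        config=config,
        epochs_run=clf.epochs_run_,
        diverged=False,
        evaluation_mode=evaluation_mode,
    )


def cascade_predict(
    ct_model,
    histo_model,
    ct_image,
    histo_image=None,
    tumor_label: str = "Tumor",
) -> dict:
    """Two-stage diagnosis: CT triage, then histopathology grading.

    Stage 1 classifies the CT image.  A tumor diagnosis routes the case to
    stage 2, which grades the histopathology slide when one is supplied
    (otherwise the record is flagged ``grading pending``); a normal
    diagnosis needs no further grading, and stone/cyst cases are routed to
    their own treatments.
    """
    ct_image = np.asarray(ct_image, dtype=float)
    stage1 = ct_model.predict(ct_image[None])[0]
    record = {"stage1": stage1, "grade": None, "pending": False}
    if str(stage1) == tumor_label:
        if histo_image is None:
            record["pending"] = True
            record["note"] = "grading pending"
        else:
            if histo_model is None:
                record["pending"] = True
                record["note"] = "grading pending"
            else:
                histo_image = np.asarray(histo_image, dtype=float)
                record["grade"] = histo_model.predict(histo_image[None])[0]
                record["note"] = "graded"
    elif str(stage1) == "Normal":
        record["note"] = "no further grading"
    else:
        record["note"] = "other treatments"
    return record
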