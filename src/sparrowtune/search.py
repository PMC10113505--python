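"""End-to-end hyperparameter search: data pipeline + codec + fitness + SpaSA.

A run executes: (1) load or generate the labeled image set, (2) equalize
class sizes by augmentation, (3) stratified train/validation/test split —
by default grouped by source image so augmented copies never leak across
partitions, (4) the sparrow search loop where each fitness call decodes a
solution vector into training hyperparameters, trains a classifier and
scores it, and (5) a final report.  Every source of randomness derives
from the single run seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator

from . import codec as codec_mod
from .codec import AugmentationConfig, SearchSpace, TrainingConfig, decode, describe
from .fitness import FitnessResult, TransferImageClassifier, cascade_predict, evaluate_fitness
from .fixtures import FixtureSpec, generate_image_set
from .pipeline import (
    LabeledImageSet,
    balance_by_augmentation,
    load_image_directory,
    resize_image,
    split_dataset,
)
from .spasa import SpaSAConfig, SparrowSearchOptimizer

__all__ = [
    "RunConfig",
    "RunResult",
    "SparrowHyperparameterSearch",
    "run_search",
    "run_cascade",
    "DEFAULT_BALANCE_AUGMENTATION",
]

#: Augmentation used for the one-off class balancing pass: moderate
#: magnitudes from the middle of the search ranges, both flips enabled.
DEFAULT_BALANCE_AUGMENTATION = AugmentationConfig(
    rotation_deg=20,
    width_shift=0.1,
    height_shift=0.1,
    shear=0.1,
    zoom=0.1,
    horizontal_flip=True,
    vertical_flip=True,
    brightness_range=(0.8, 1.2),
)


@dataclass
class RunConfig:
    """Everything one reproducible search run needs."""

    dataset: Union[str, Path, FixtureSpec, LabeledImageSet]
    backbone: str = "surrogate-tiny"
    spasa: SpaSAConfig = field(default_factory=SpaSAConfig)
    space: SearchSpace = field(default_factory=codec_mod.default_search_space)
    train_ratio: float = 0.85
    validation_ratio: float = 0.15
    epochs: int = 5
    evaluation_mode: str = "holdout"
    balance: bool = True
    balance_augmentation: AugmentationConfig = field(
        default_factory=lambda: DEFAULT_BALANCE_AUGMENTATION
    )
    image_size: Optional[int] = None
    group_split_by_source: bool = True
    output_dir: Optional[Union[str, Path]] = None
    seed: Optional[int] = None


@dataclass
class RunResult:
    """Outcome of a search run."""

    best_config: TrainingConfig
    best_score: float
    best_solution: list
    history: list
    evaluations: list
    n_evaluations: int
    test_report: Optional[dict] = None
    environment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best_config": describe(self.best_config),
            "best_score": self.best_score,
            "best_solution": list(self.best_solution),
            "history": list(self.history),
            "n_evaluations": self.n_evaluations,
            "test_report": self.test_report,
            "environment": self.environment,
        }


def _derive_seeds(seed) -> dict:
    ss = np.random.SeedSequence(seed)
    vals = ss.generate_state(4)
    return {
        "optimizer": int(vals[0]) % (2**31),
        "balance": int(vals[1]) % (2**31),
        "split": int(vals[2]) % (2**31),
        "eval_base": int(vals[3]) % (2**31),
    }


class SparrowHyperparameterSearch(BaseEstimator):
    """Sparrow-search hyperparameter tuning as a scikit-learn estimator.

    ``fit(X, y)`` takes an ``(n, H, W, 3)`` image array with labels,
    splits off a validation share, runs the sparrow search over the
    hyperparameter space and refits ``best_estimator_`` with the winning
    configuration.  Mirrors the shape of sklearn's randomized search:
    fitted attributes ``best_config_``, ``best_score_``, ``best_params_``,
    ``history_``, ``evaluations_``, ``best_estimator_``.
    """

    def __init__(
        self,
        backbone: str = "surrogate-tiny",
        population_size: int = 10,
        n_iterations: int = 10,
        epochs: int = 5,
        producer_ratio: float = 0.20,
        scout_ratio: float = 0.20,
        safety_threshold: float = 0.8,
        validation_ratio: float = 0.15,
        evaluation_mode: str = "holdout",
        reduced_space: bool = False,
        random_state=None,
    ):
        self.backbone = backbone
        self.population_size = population_size
        self.n_iterations = n_iterations
        self.epochs = epochs
        self.producer_ratio = producer_ratio
        self.scout_ratio = scout_ratio
        self.safety_threshold = safety_threshold
        self.validation_ratio = validation_ratio
        self.evaluation_mode = evaluation_mode
        self.reduced_space = reduced_space
        self.random_state = random_state

    def _space(self) -> SearchSpace:
        space = codec_mod.default_search_space()
        return replace(space, reduced=True) if self.reduced_space else space

    def fit(self, X, y) -> "SparrowHyperparameterSearch":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        seeds = _derive_seeds(self.random_state)
        rng = np.random.default_rng(seeds["split"])
        n = len(X)
        order = rng.permutation(n)
        n_val = max(1, int(round(self.validation_ratio * n)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        train = (X[tr_idx], y[tr_idx])
        val = (X[val_idx], y[val_idx])
        spasa = SpaSAConfig(
            population_size=self.population_size,
            max_iterations=self.n_iterations,
            producer_ratio=self.producer_ratio,
            scout_ratio=self.scout_ratio,
            safety_threshold=self.safety_threshold,
            seed=seeds["optimizer"],
            maximize=True,
        )
        best_config, best_score, best_solution, history, evals = _search(
            train,
            val,
            space=self._space(),
            backbone=self.backbone,
            spasa=spasa,
            epochs=self.epochs,
            evaluation_mode=self.evaluation_mode,
            eval_seed_base=seeds["eval_base"],
        )
        self.best_config_ = best_config
        self.best_score_ = best_score
        self.best_solution_ = best_solution
        self.best_params_ = describe(best_config)
        self.history_ = history
        self.evaluations_ = evals
        self.best_estimator_ = TransferImageClassifier.from_config(
            best_config,
            backbone=self.backbone,
            epochs=self.epochs,
            random_state=seeds["eval_base"],
        ).fit(X, y)
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)


def _search(
    train,
    val,
    space: SearchSpace,
    backbone: str,
    spasa: SpaSAConfig,
    epochs: int,
    evaluation_mode: str,
    eval_seed_base: int,
    log_file=None,
):
    evaluations: list = []
    counter = {"n": 0}

    def fitness(solution: np.ndarray) -> float:
        cfg = decode(solution, space)
        eval_seed = (eval_seed_base + counter["n"]) % (2**31)
        result = evaluate_fitness(
            backbone,
            cfg,
            train,
            val,
            epochs=epochs,
            seed=eval_seed,
            evaluation_mode=evaluation_mode,
        )
        entry = {
            "index": counter["n"],
            "score": result.score,
            "diverged": result.diverged,
            "epochs_run": result.epochs_run,
            "evaluation_mode": result.evaluation_mode,
            "config": describe(cfg),
            "solution": [float(v) for v in solution],
        }
        evaluations.append(entry)
        if log_file is not None:
            log_file.write(json.dumps(entry) + "\n")
            log_file.flush()
        counter["n"] += 1
        return result.score

    optimizer = SparrowSearchOptimizer(spasa, space.dimension)
    res = optimizer.run(fitness)
    best_config = decode(res.best_solution, space)
    return (
        best_config,
        res.best_score,
        [float(v) for v in res.best_solution],
        res.history,
        evaluations,
    )


def _resolve_dataset(config: RunConfig) -> LabeledImageSet:
    ds = config.dataset
    if isinstance(ds, LabeledImageSet):
        data = ds
    elif isinstance(ds, FixtureSpec):
        data = generate_image_set(ds)
    else:
        data = load_image_directory(ds)
    if config.image_size is not None:
        data = LabeledImageSet(
            images=[resize_image(im, config.image_size) for im in data.images],
            labels=list(data.labels),
            class_names=list(data.class_names),
            provenance=list(data.provenance),
            source_index=list(data.source_index),
        )
    return data


def run_search(config: RunConfig) -> RunResult:
    """Execute a full search run; see the module docstring for the stages."""
    import sklearn

    seeds = _derive_seeds(config.seed)
    data = _resolve_dataset(config)
    if config.balance:
        data = balance_by_augmentation(
            data, config.balance_augmentation, seed=seeds["balance"]
        )
    train, val, test = split_dataset(
        data,
        train_ratio=config.train_ratio,
        seed=seeds["split"],
        validation_ratio=config.validation_ratio,
        group_by_source=config.group_split_by_source,
    )
    out_dir = Path(config.output_dir) if config.output_dir else None
    log_file = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_file = open(out_dir / "evaluations.jsonl", "w")
    try:
        best_config, best_score, best_solution, history, evals = _search(
            train,
            val,
            space=config.space,
            backbone=config.backbone,
            spasa=replace(config.spasa, seed=seeds["optimizer"]),
            epochs=config.epochs,
            evaluation_mode=config.evaluation_mode,
            eval_seed_base=seeds["eval_base"],
            log_file=log_file,
        )
    finally:
        if log_file is not None:
            log_file.close()
    # final report on the untouched test partition
    final = evaluate_fitness(
        config.backbone,
        best_config,
        train,
        val,
        evaluation_set=test,
        epochs=config.epochs,
        seed=seeds["eval_base"],
    )
    test_report = (
        None
        if final.metric_report is None
        else final.metric_report.as_percentages()
    )
    result = RunResult(
        best_config=best_config,
        best_score=best_score,
        best_solution=best_solution,
        history=history,
        evaluations=evals,
        n_evaluations=len(evals),
        test_report=test_report,
        environment={
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
            "seed": config.seed,
            "backbone": config.backbone,
            "evaluation_mode": config.evaluation_mode,
        },
    )
    if out_dir is not None:
        (out_dir / "run_result.json").write_text(json.dumps(result.to_dict(), indent=2))
    return result


def run_cascade(
    ct_model,
    histo_model,
    ct_images,
    histo_images=None,
    tumor_label: str = "Tumor",
) -> list:
    """Apply the two-stage diagnosis to a batch of CT images.

    ``histo_images`` may be None (every tumor case is flagged pending), a
    single slide, or a list parallel to ``ct_images``.  Returns one record
    per image.
    """
    records = []
    for i, ct in enumerate(ct_images):
        histo = None
        if histo_images is not None:
            histo = histo_images[i] if isinstance(histo_images, (list, tuple)) else histo_images
        records.append(
            cascade_predict(ct_model, histo_model, ct, histo, tumor_label=tumor_label)
        )
    return records
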