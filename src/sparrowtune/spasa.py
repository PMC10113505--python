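"""Sparrow search algorithm (SpaSA) over the unit hypercube.

The sparrow search algorithm is a swarm metaheuristic modelled on sparrow
foraging: at each iteration the fittest fraction of the population act as
*producers* (discoverers) that lead the search, the remainder act as
*scroungers* (followers) that track the best producer, and a random subset
act as *scouts* whose anti-predation jumps help escape local optima.

This module implements the optimizer generically over any fitness callable
on ``[0, 1]^D``; hyperparameter decoding lives in :mod:`sparrowtune.codec`.
All randomness flows through a single :class:`numpy.random.Generator`, and
every stochastic quantity consumed by one population update is collected in
an explicit :class:`UpdateRandoms` record so the update equations themselves
are deterministic, testable functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SpaSAConfig",
    "Population",
    "UpdateRandoms",
    "OptimizeResult",
    "SparrowSearchOptimizer",
    "initialize_population",
    "sort_and_extract",
    "update_discoverers",
    "update_followers",
    "update_scouts",
    "optimize",
]


@dataclass(frozen=True)
class SpaSAConfig:
    """Settings of one sparrow-search run.

    Parameters
    ----------
    population_size : int
        Number of sparrows ``N``; at least 2.  Default 10.
    max_iterations : int
        Number of update rounds ``T_max``.  Default 10.
    producer_ratio : float
        Fraction of the (sorted) population acting as producers, ``PD``.
        The producer count is ``max(1, round(PD * N))``.  Default 0.20.
    scout_ratio : float
        Fraction acting as scouts, ``SD``; scouts are sampled uniformly
        without replacement each iteration.  Default 0.20.
    safety_threshold : float
        Safety value ``ST`` in ``[0.5, 1]`` compared against the alarm value
        ``R2``: while ``R2 < ST`` producers exploit smoothly, otherwise the
        flock relocates with a normal perturbation.  Default 0.8.
    epsilon : float
        Small constant guarding the scout division.  Default 1e-50.
    seed : int, optional
        Seed for the optimizer's random generator.
    maximize : bool
        Whether larger fitness is better (True for accuracy).  Default True.
    """

    population_size: int = 10
    max_iterations: int = 10
    producer_ratio: float = 0.20
    scout_ratio: float = 0.20
    safety_threshold: float = 0.8
    epsilon: float = 1e-50
    seed: Optional[int] = None
    maximize: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if not (0.0 < self.producer_ratio < 1.0):
            raise ValueError("producer_ratio must lie in (0, 1)")
        if not (0.0 < self.scout_ratio < 1.0):
            raise ValueError("scout_ratio must lie in (0, 1)")
        if self.producer_ratio + self.scout_ratio > 1.0:
            raise ValueError("producer_ratio + scout_ratio must not exceed 1")
        if not (0.5 <= self.safety_threshold <= 1.0):
            raise ValueError("safety_threshold must lie in [0.5, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_producers(self) -> int:
        return max(1, round(self.producer_ratio * self.population_size))

    @property
    def n_scouts(self) -> int:
        return max(1, round(self.scout_ratio * self.population_size))


@dataclass
class Population:
    """Candidate solutions with parallel fitness scores.

    ``solutions`` is an ``(N, D)`` array with every entry in ``[0, 1]``.
    After :func:`sort_and_extract` the rows are ordered best-first and the
    ``best`` / ``worst`` / ``producer_best`` snapshots (used by the update
    equations) are populated.
    """

    solutions: np.ndarray
    scores: Optional[np.ndarray] = None
    sorted: bool = False
    best: Optional[np.ndarray] = None
    worst: Optional[np.ndarray] = None
    producer_best: Optional[np.ndarray] = None
    best_score: Optional[float] = None
    worst_score: Optional[float] = None

    @property
    def size(self) -> int:
        return self.solutions.shape[0]

    @property
    def dimension(self) -> int:
        return self.solutions.shape[1]

    def copy(self) -> "Population":
        return Population(
            solutions=self.solutions.copy(),
            scores=None if self.scores is None else self.scores.copy(),
            sorted=self.sorted,
            best=None if self.best is None else self.best.copy(),
            worst=None if self.worst is None else self.worst.copy(),
            producer_best=(
                None if self.producer_best is None else self.producer_best.copy()
            ),
            best_score=self.best_score,
            worst_score=self.worst_score,
        )


@dataclass
class UpdateRandoms:
    """Every random draw consumed by one full population update.

    ``r2`` is the alarm value, drawn once per call.  ``alphas`` holds one
    uniform ``(0, 1]`` draw per producer; ``q_producers``/``q_followers``
    are standard-normal ``(n, D)`` matrices; ``a_signs`` holds the follower
    direction matrices ``A`` with entries in ``{-1, +1}`` (so the pseudo
    inverse is exactly ``A^T / D``); ``scout_indices`` selects scouts
    without replacement; ``betas`` and ``ks`` are the per-scout step-size
    and direction draws.
    """

    r2: float
    alphas: np.ndarray
    q_producers: np.ndarray
    q_followers: np.ndarray
    a_signs: np.ndarray
    scout_indices: np.ndarray
    betas: np.ndarray
    ks: np.ndarray

    @classmethod
    def draw(
        cls, rng: np.random.Generator, config: SpaSAConfig, dimension: int
    ) -> "UpdateRandoms":
        n = config.population_size
        n_prod = config.n_producers
        n_foll = n - n_prod
        n_scout = config.n_scouts
        r2 = float(rng.uniform(0.0, 1.0))
        alphas = 1.0 - rng.uniform(0.0, 1.0, size=n_prod)  # in (0, 1]
        q_producers = rng.standard_normal(size=(n_prod, dimension))
        q_followers = rng.standard_normal(size=(max(n_foll, 0), dimension))
        a_signs = rng.choice([-1.0, 1.0], size=(max(n_foll, 0), dimension))
        scout_indices = rng.choice(n, size=n_scout, replace=False)
        betas = rng.standard_normal(size=n_scout)
        ks = rng.uniform(-1.0, 1.0, size=n_scout)
        return cls(
            r2=r2,
            alphas=alphas,
            q_producers=q_producers,
            q_followers=q_followers,
            a_signs=a_signs,
            scout_indices=scout_indices,
            betas=betas,
            ks=ks,
        )


@dataclass
class OptimizeResult:
    """Outcome of a full sparrow-search run."""

    best_solution: np.ndarray
    best_score: float
    history: list[float]
    n_evaluations: int


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def initialize_population(
    config: SpaSAConfig,
    dimension: int,
    rng: Optional[np.random.Generator] = None,
) -> Population:
    """Seed ``N`` solutions uniformly at random in ``[0, 1]^D``."""
    if dimension < 1:
        raise ValueError("dimension must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    solutions = rng.uniform(0.0, 1.0, size=(config.population_size, dimension))
    return Population(solutions=solutions)


def sort_and_extract(pop: Population, maximize: bool = True) -> Population:
    """Order the population best-first and snapshot best/worst positions.

    The sort is stable, so equal scores keep their original order.  For
    maximization the scores end up non-increasing; for minimization
    non-decreasing.  The best producer position (the top row, which leads
    the followers) and the worst position are recorded on the population.
    """
    if pop.scores is None:
        raise RuntimeError("population scores must be computed before sorting")
    if len(pop.scores) != pop.size:
        raise ValueError("scores and solutions are not parallel")
    keys = -pop.scores if maximize else pop.scores
    order = np.argsort(keys, kind="stable")
    out = Population(
        solutions=pop.solutions[order].copy(),
        scores=pop.scores[order].copy(),
        sorted=True,
    )
    out.best = out.solutions[0].copy()
    out.worst = out.solutions[-1].copy()
    out.producer_best = out.solutions[0].copy()
    out.best_score = float(out.scores[0])
    out.worst_score = float(out.scores[-1])
    return out


def _require_sorted(pop: Population) -> None:
    if not pop.sorted or pop.best is None:
        raise RuntimeError("population must be sorted (sort_and_extract) first")


def update_discoverers(
    pop: Population,
    config: SpaSAConfig,
    t: int,
    randoms: Optional[UpdateRandoms] = None,
    rng: Optional[np.random.Generator] = None,
) -> Population:
    """Producer update: the top ``PD`` rows explore or relocate.

    While the alarm value ``R2`` (one draw per call) stays below the safety
    threshold ``ST``, each producer decays multiplicatively by
    ``exp(-t / (alpha * T_max))`` with its own uniform ``alpha``; otherwise
    every producer takes an independent standard-normal step per coordinate.
    Results are clamped back into the unit cube.
    """
    _require_sorted(pop)
    if not (1 <= t <= config.max_iterations):
        raise ValueError("iteration t must lie in [1, T_max]")
    if randoms is None:
        randoms = UpdateRandoms.draw(
            rng if rng is not None else np.random.default_rng(config.seed),
            config,
            pop.dimension,
        )
    out = pop.copy()
    n_prod = config.n_producers
    if randoms.r2 < config.safety_threshold:
        decay = np.exp(-t / (randoms.alphas * config.max_iterations))
        out.solutions[:n_prod] = out.solutions[:n_prod] * decay[:, None]
    else:
        out.solutions[:n_prod] = out.solutions[:n_prod] + randoms.q_producers
    out.solutions[:n_prod] = _clamp(out.solutions[:n_prod])
    return out


def update_followers(
    pop: Population,
    config: SpaSAConfig,
    randoms: Optional[UpdateRandoms] = None,
    rng: Optional[np.random.Generator] = None,
) -> Population:
    """Scrounger update: the non-producers chase the best producer.

    Followers occupy sorted positions ``PD+1 .. N`` (1-based).  A follower
    whose population position ``i`` exceeds ``N/2`` (the hungriest, lowest
    ranked half) jumps to ``Q * exp((X_worst - X) / i^2)`` element-wise;
    the rest move to ``X_P + |X - X_P| * A+`` element-wise, where ``A`` has
    random ``+-1`` entries and ``A+ = A^T / D``.  Clamped to ``[0, 1]``.
    """
    _require_sorted(pop)
    if randoms is None:
        randoms = UpdateRandoms.draw(
            rng if rng is not None else np.random.default_rng(config.seed),
            config,
            pop.dimension,
        )
    out = pop.copy()
    n = config.population_size
    n_prod = config.n_producers
    d = pop.dimension
    best_producer = pop.producer_best
    worst = pop.worst
    for k in range(n - n_prod):
        i = n_prod + k + 1  # 1-based population position
        x = out.solutions[i - 1]
        if i > 0.5 * n:
            newx = randoms.q_followers[k] * np.exp((worst - x) / (i * i))
        else:
            newx = best_producer + np.abs(x - best_producer) * (
                randoms.a_signs[k] / d
            )
        out.solutions[i - 1] = _clamp(newx)
    return out


def update_scouts(
    pop: Population,
    config: SpaSAConfig,
    randoms: Optional[UpdateRandoms] = None,
    rng: Optional[np.random.Generator] = None,
) -> Population:
    """Anti-predation update of ``SD`` randomly chosen sparrows.

    A scout whose fitness differs from the best score moves towards the
    best position with a normal step-size ``beta``; a scout already at the
    best fitness steps away from the worst position scaled by
    ``K / (f_i - f_w + eps)``.  Clamped to ``[0, 1]``.
    """
    _require_sorted(pop)
    if randoms is None:
        randoms = UpdateRandoms.draw(
            rng if rng is not None else np.random.default_rng(config.seed),
            config,
            pop.dimension,
        )
    out = pop.copy()
    best = pop.best
    worst = pop.worst
    for j, idx in enumerate(randoms.scout_indices):
        x = out.solutions[idx]
        f_i = float(pop.scores[idx])
        if f_i != pop.best_score:
            newx = best + randoms.betas[j] * np.abs(x - best)
        else:
            newx = x + randoms.ks[j] * (
                np.abs(x - worst) / ((f_i - pop.worst_score) + config.epsilon)
            )
        out.solutions[idx] = _clamp(newx)
    return out


def full_update(
    pop: Population,
    config: SpaSAConfig,
    t: int,
    randoms: UpdateRandoms,
) -> Population:
    """One complete sorted-population update (producers, followers, scouts)."""
    pop = update_discoverers(pop, config, t, randoms=randoms)
    pop = update_followers(pop, config, randoms=randoms)
    pop = update_scouts(pop, config, randoms=randoms)
    return pop


class SparrowSearchOptimizer:
    """Stateful sparrow-search driver with JSON checkpointing.

    Examples
    --------
    >>> cfg = SpaSAConfig(population_size=10, max_iterations=20, seed=0,
    ...                   maximize=False)
    >>> opt = SparrowSearchOptimizer(cfg, dimension=5)
    >>> res = opt.run(lambda x: float(((x - 0.5) ** 2).sum()))
    >>> res.best_score <= res.history[0]
    True
    """

    def __init__(self, config: SpaSAConfig, dimension: int):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.config = config
        self.dimension = dimension
        self.rng = np.random.default_rng(config.seed)
        self.population = initialize_population(config, dimension, rng=self.rng)
        self.t = 0
        self.best_solution: Optional[np.ndarray] = None
        self.best_score: Optional[float] = None
        self.history: list[float] = []
        self.n_evaluations = 0

    def _better(self, a: float, b: Optional[float]) -> bool:
        if b is None:
            return True
        return a > b if self.config.maximize else a < b

    def _evaluate(self, fitness: Callable[[np.ndarray], float]) -> None:
        scores = np.empty(self.population.size)
        for i, sol in enumerate(self.population.solutions):
            try:
                scores[i] = float(fitness(sol))
            except Exception as exc:  # surface location of the failure
                raise RuntimeError(
                    f"fitness evaluation failed at iteration {self.t}, "
                    f"solution index {i}"
                ) from exc
            self.n_evaluations += 1
            if self._better(scores[i], self.best_score):
                self.best_score = float(scores[i])
                self.best_solution = sol.copy()
        self.population.scores = scores
        self.population.sorted = False

    def step(self, fitness: Callable[[np.ndarray], float]) -> float:
        """Run one iteration: evaluate all, sort, update. Returns best-ever."""
        if self.t >= self.config.max_iterations:
            raise RuntimeError("optimizer already ran max_iterations steps")
        self.t += 1
        self._evaluate(fitness)
        self.population = sort_and_extract(self.population, self.config.maximize)
        randoms = UpdateRandoms.draw(self.rng, self.config, self.dimension)
        self.population = full_update(self.population, self.config, self.t, randoms)
        self.history.append(self.best_score)
        return self.best_score

    def run(self, fitness: Callable[[np.ndarray], float]) -> OptimizeResult:
        while self.t < self.config.max_iterations:
            self.step(fitness)
        return OptimizeResult(
            best_solution=self.best_solution.copy(),
            best_score=self.best_score,
            history=list(self.history),
            n_evaluations=self.n_evaluations,
        )

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict:
        """Full optimizer state as a JSON-serializable dict."""
        return {
            "config": {
                "population_size": self.config.population_size,
                "max_iterations": self.config.max_iterations,
                "producer_ratio": self.config.producer_ratio,
                "scout_ratio": self.config.scout_ratio,
                "safety_threshold": self.config.safety_threshold,
                "epsilon": self.config.epsilon,
                "seed": self.config.seed,
                "maximize": self.config.maximize,
            },
            "dimension": self.dimension,
            "t": self.t,
            "rng_state": self.rng.bit_generator.state,
            "solutions": self.population.solutions.tolist(),
            "scores": (
                None
                if self.population.scores is None
                else self.population.scores.tolist()
            ),
            "sorted": self.population.sorted,
            "best_solution": (
                None if self.best_solution is None else self.best_solution.tolist()
            ),
            "best_score": self.best_score,
            "history": list(self.history),
            "n_evaluations": self.n_evaluations,
        }

    def to_json(self) -> str:
        return json.dumps(self.state_dict())

    @classmethod
    def from_state(cls, state: dict) -> "SparrowSearchOptimizer":
        config = SpaSAConfig(**state["config"])
        opt = cls(config, state["dimension"])
        opt.t = state["t"]
        opt.rng.bit_generator.state = state["rng_state"]
        pop = Population(solutions=np.asarray(state["solutions"], dtype=float))
        if state["scores"] is not None:
            pop.scores = np.asarray(state["scores"], dtype=float)
        pop.sorted = state["sorted"]
        if pop.sorted:
            pop = sort_and_extract(pop, config.maximize)
        opt.population = pop
        if state["best_solution"] is not None:
            opt.best_solution = np.asarray(state["best_solution"], dtype=float)
        opt.best_score = state["best_score"]
        opt.history = list(state["history"])
        opt.n_evaluations = state["n_evaluations"]
        return opt

    @classmethod
    def from_json(cls, payload: str) -> "SparrowSearchOptimizer":
        return cls.from_state(json.loads(payload))


def optimize(
    fitness: Callable[[np.ndarray], float],
    config: SpaSAConfig,
    dimension: int,
) -> OptimizeResult:
    """Run a full sparrow search; thin wrapper over SparrowSearchOptimizer."""
    return SparrowSearchOptimizer(config, dimension).run(fitness)
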