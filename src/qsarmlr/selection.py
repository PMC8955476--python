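"""Descriptor-subset search: genetic algorithm and exhaustive-enumeration oracle.

Chromosomes are binary inclusion masks over the descriptor pool, capped at
``max_subset_size`` by random repair. Fitness is either Friedman's
lack-of-fit (minimised) or Q2 leave-one-out (maximised). The exhaustive
search evaluates every subset up to the size cap and is the exact optimum the
GA is tested against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import DatasetError, QsarDataset
from .mlr import FitStatistics, fit_ols
from .validation import CrossValReport, q2_loo

__all__ = ["GAConfig", "ModelCandidate", "ga_select", "exhaustive_select", "rank_models"]

_FITNESSES = ("min_LOF", "max_Q2LOO")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults mirror common QSAR practice: population 200, per-chromosome
    mutation probability 0.1, up to 2000 generations with early stop after
    200 stagnant generations (set ``early_stop_generations=None`` to run the
    full budget), LOF smoothness d = 1.0, subsets capped at 4 descriptors.
    """

    population_size: int = 200
    mutation_probability: float = 0.1
    max_generations: int = 2000
    lof_smoothness: float = 1.0
    max_subset_size: int = 4
    fitness: str = "min_LOF"
    elitism: int = 10
    seed: int = 0
    crossover_probability: float = 1.0
    early_stop_generations: int | None = 200
    n_best: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.mutation_probability < 1.0):
            raise ValueError("mutation_probability must lie in (0, 1)")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_subset_size < 1:
            raise ValueError("max_subset_size must be at least 1")
        if self.fitness not in _FITNESSES:
            raise ValueError(f"fitness must be one of {_FITNESSES}")


@dataclass
class ModelCandidate:
    """A descriptor subset with its fitness; reports attached by rank_models."""

    subset: tuple[str, ...]
    fitness: float
    fitness_name: str
    fit_statistics: FitStatistics | None = None
    crossval: CrossValReport | None = None

    def __post_init__(self) -> None:
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("subset names must be unique")


class _Evaluator:
    """Memoised subset -> score map (score is always maximised)."""

    def __init__(self, train: QsarDataset, config_fitness: str, lof_smoothness: float):
        self.train = train
        self.fitness = config_fitness
        self.lof_smoothness = lof_smoothness
        self._cache: dict[frozenset, float] = {}

    def score(self, subset: Sequence[str]) -> float:
        key = frozenset(subset)
        if key not in self._cache:
            names = sorted(subset)
            try:
                if self.fitness == "min_LOF":
                    _, stats = fit_ols(self.train, names, lof_smoothness=self.lof_smoothness)
                    value = -stats.LOF
                else:
                    value = q2_loo(self.train, names).Q2
            except Exception:
                value = -math.inf  # rank-deficient or otherwise unfittable subset
            self._cache[key] = value
        return self._cache[key]

    def raw_fitness(self, score: float) -> float:
        return -score if self.fitness == "min_LOF" else score


def _repair(mask: np.ndarray, max_size: int, rng: np.random.Generator) -> None:
    on = np.flatnonzero(mask)
    while on.size > max_size:
        drop = rng.choice(on)
        mask[drop] = False
        on = np.flatnonzero(mask)
    if on.size == 0:
        mask[rng.integers(mask.size)] = True


def ga_select(train: QsarDataset, config: GAConfig | None = None) -> list[ModelCandidate]:
    """Evolve descriptor subsets; returns deduplicated top candidates, best first.

    Roulette (fitness-proportional) parent selection, one-point crossover,
    per-chromosome mutation flipping one random bit, size repair, and elitism.
    Fully reproducible from ``config.seed``.
    """
    if config is None:
        config = GAConfig()
    pool = list(train.descriptor_names)
    m = len(pool)
    if m < 1:
        raise DatasetError("empty descriptor pool")
    if config.max_subset_size > m:
        raise DatasetError(
            f"max_subset_size {config.max_subset_size} exceeds pool size {m}"
        )
    X = train.descriptor_matrix()
    if np.all(np.std(X, axis=0) == 0):
        raise DatasetError("all descriptors are constant")
    rng = np.random.default_rng(config.seed)
    ev = _Evaluator(train, config.fitness, config.lof_smoothness)

    def as_subset(mask: np.ndarray) -> tuple[str, ...]:
        return tuple(pool[j] for j in np.flatnonzero(mask))

    # initial population: random masks of random size <= cap
    population = []
    for _ in range(config.population_size):
        size = int(rng.integers(1, config.max_subset_size + 1))
        mask = np.zeros(m, dtype=bool)
        mask[rng.choice(m, size=size, replace=False)] = True
        population.append(mask)

    scores = np.array([ev.score(as_subset(mk)) for mk in population])
    best_score = scores.max()
    stagnant = 0
    generations_run = 0
    for gen in range(config.max_generations):
        generations_run = gen + 1
        order = np.argsort(-scores, kind="stable")
        elite = [population[i].copy() for i in order[: config.elitism]]
        # roulette weights: shift so the worst finite member gets weight ~0
        finite = np.isfinite(scores)
        w = np.where(finite, scores, np.nan)
        lo = np.nanmin(w) if finite.any() else 0.0
        weights = np.where(finite, scores - lo, 0.0) + 1e-12
        probs = weights / weights.sum()
        children = list(elite)
        while len(children) < config.population_size:
            i, j = rng.choice(len(population), size=2, p=probs)
            a, b = population[i].copy(), population[j].copy()
            if rng.random() < config.crossover_probability and m > 1:
                cut = int(rng.integers(1, m))
                a = np.concatenate([population[i][:cut], population[j][cut:]])
            if rng.random() < config.mutation_probability:
                flip = int(rng.integers(m))
                a[flip] = ~a[flip]
            _repair(a, config.max_subset_size, rng)
            children.append(a)
        population = children[: config.population_size]
        scores = np.array([ev.score(as_subset(mk)) for mk in population])
        if scores.max() > best_score + 1e-15:
            best_score = scores.max()
            stagnant = 0
        else:
            stagnant += 1
            if (
                config.early_stop_generations is not None
                and stagnant >= config.early_stop_generations
            ):
                break

    # deduplicated ranking over everything ever evaluated
    ranked = sorted(ev._cache.items(), key=lambda kv: -kv[1])
    out = []
    for key, score in ranked[: config.n_best]:
        if not math.isfinite(score):
            continue
        out.append(
            ModelCandidate(
                subset=tuple(sorted(key)),
                fitness=ev.raw_fitness(score),
                fitness_name=config.fitness,
            )
        )
    return out


def exhaustive_select(
    train: QsarDataset,
    max_subset_size: int = 4,
    fitness: str = "min_LOF",
    lof_smoothness: float = 1.0,
    cap: int = 10**6,
    n_best: int = 10,
) -> list[ModelCandidate]:
    """Evaluate every descriptor subset up to the size cap; exact optimum.

    Refuses (with the count) when the number of subsets exceeds ``cap``.
    """
    if fitness not in _FITNESSES:
        raise ValueError(f"fitness must be one of {_FITNESSES}")
    pool = list(train.descriptor_names)
    m = len(pool)
    total = sum(math.comb(m, k) for k in range(1, min(max_subset_size, m) + 1))
    if total > cap:
        raise DatasetError(
            f"exhaustive search over {total} subsets exceeds the cap of {cap}"
        )
    ev = _Evaluator(train, fitness, lof_smoothness)
    results = []
    for k in range(1, min(max_subset_size, m) + 1):
        for combo in itertools.combinations(pool, k):
            results.append((combo, ev.score(combo)))
    results.sort(key=lambda t: -t[1])
    out = []
    for combo, score in results[:n_best]:
        if not math.isfinite(score):
            continue
        out.append(
            ModelCandidate(
                subset=tuple(sorted(combo)),
                fitness=ev.raw_fitness(score),
                fitness_name=fitness,
            )
        )
    if not out:
        raise DatasetError("no fittable subset found")
    return out


# metric name -> (extractor, higher_is_better)
_METRICS = {
    "Q2_LOO": (lambda c: c.crossval.Q2, True),
    "R2": (lambda c: c.fit_statistics.R2, True),
    "R2_adj": (lambda c: c.fit_statistics.R2_adj, True),
    "CCC": (lambda c: c.fit_statistics.CCC, True),
    "LOF": (lambda c: c.fit_statistics.LOF, False),
    "RMSE": (lambda c: c.fit_statistics.RMSE, False),
    "s": (lambda c: c.fit_statistics.s, False),
}


def rank_models(
    candidates: Sequence[ModelCandidate],
    criteria: Sequence[str],
    train: QsarDataset,
) -> list[ModelCandidate]:
    """Attach fit and cross-validation reports and sort lexicographically.

    ``criteria`` are metric names (``Q2_LOO``, ``R2``, ``LOF``, ...) applied
    in order; the sort is stable, so ties preserve input order.
    """
    if not candidates:
        raise DatasetError("no candidates to rank")
    unknown = [c for c in criteria if c not in _METRICS]
    if unknown:
        raise DatasetError(f"unknown ranking metrics {unknown}; known: {sorted(_METRICS)}")
    enriched = []
    for cand in candidates:
        names = list(cand.subset)
        _, stats = fit_ols(train, names)
        cv = q2_loo(train, names)
        enriched.append(
            ModelCandidate(
                subset=cand.subset,
                fitness=cand.fitness,
                fitness_name=cand.fitness_name,
                fit_statistics=stats,
                crossval=cv,
            )
        )
    out = list(enriched)
    for crit in reversed(list(criteria)):
        extract, higher = _METRICS[crit]
        out.sort(key=lambda c: extract(c) * (-1 if higher else 1))
    return out
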