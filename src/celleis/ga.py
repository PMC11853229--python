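"""Seeded real-coded genetic algorithm for circuit-parameter fitting.

Component values span many decades, so the genome lives in log10-space of
the physical parameters.  The algorithm is deliberately conventional:
tournament selection, blend (BLX-alpha) crossover, Gaussian mutation,
elitism of one.  All randomness flows from the configured seed, so a fixed
seed and configuration reproduce the run exactly.  An optional local
least-squares polish of the best individual is applied by callers that
want refined point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["GAConfig", "GAResult", "minimize_ga"]


@dataclass(frozen=True)
class GAConfig:
    """Settings of the genetic algorithm.

    ``bounds`` are per-parameter (low, high) in physical units; the search
    runs in log10 of the parameter, so bounds must be positive.
    """

    bounds: Sequence[tuple[float, float]] = ()
    population_size: int = 100
    generations: int = 200
    seed: int = 20250214
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    tournament_size: int = 3
    blx_alpha: float = 0.3
    mutation_sigma: float = 0.15  # in log10 units

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < low < high")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1")


@dataclass
class GAResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    improved: bool
    history: np.ndarray  # best objective per generation


def minimize_ga(
    objective: Callable[[np.ndarray], float], config: GAConfig
) -> GAResult:
    """Minimize ``objective`` (physical-parameter vector -> scalar >= 0)."""
    bounds = np.asarray(config.bounds, dtype=float)
    if bounds.size == 0:
        raise ValueError("GAConfig.bounds must be provided")
    lo, hi = np.log10(bounds[:, 0]), np.log10(bounds[:, 1])
    ndim = lo.size
    rng = np.random.default_rng(config.seed)

    def decode(g: np.ndarray) -> np.ndarray:
        return 10.0 ** np.clip(g, lo, hi)

    pop = rng.uniform(lo, hi, size=(config.population_size, ndim))
    fitness = np.array([objective(decode(g)) for g in pop])
    n_eval = config.population_size
    first_best = float(fitness.min())
    history = []

    for _ in range(config.generations):
        order = np.argsort(fitness)
        elite = pop[order[0]].copy()
        elite_fit = float(fitness[order[0]])
        history.append(elite_fit)

        # tournament selection of parents
        idx = rng.integers(
            0, config.population_size,
            size=(config.population_size, config.tournament_size),
        )
        winners = idx[np.arange(config.population_size),
                      np.argmin(fitness[idx], axis=1)]
        parents = pop[winners]

        # BLX-alpha crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, config.population_size - 1, 2):
            if rng.random() < config.crossover_rate:
                p, q = parents[i], parents[i + 1]
                span = np.abs(p - q)
                c_lo = np.minimum(p, q) - config.blx_alpha * span
                c_hi = np.maximum(p, q) + config.blx_alpha * span
                children[i] = rng.uniform(c_lo, c_hi)
                children[i + 1] = rng.uniform(c_lo, c_hi)

        # gaussian mutation
        mutate = rng.random(children.shape) < config.mutation_rate
        children = children + mutate * rng.normal(
            0.0, config.mutation_sigma, size=children.shape
        )
        children = np.clip(children, lo, hi)
        children[0] = elite  # elitism

        pop = children
        fitness = np.array([objective(decode(g)) for g in pop])
        n_eval += config.population_size

    best_i = int(np.argmin(fitness))
    best_fit = float(fitness[best_i])
    return GAResult(
        x=decode(pop[best_i]),
        fun=best_fit,
        n_evaluations=n_eval,
        improved=best_fit < first_best,
        history=np.asarray(history),
    )
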