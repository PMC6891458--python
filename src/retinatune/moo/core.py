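"""Shared machinery for the population-based multi-objective optimisers.

All five algorithms operate on the same 6-gene mixed-integer chromosome
(continuous internal representation, rounded/clipped at evaluation time) and
minimise a 4-component objective vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ..metrics import ObjectiveVector
from ..retina import (
    CHROMOSOME_BOUNDS,
    GENE_NAMES,
    INTEGER_GENES,
    Chromosome,
    clip_chromosome,
)

__all__ = [
    "LOWER",
    "UPPER",
    "Individual",
    "AlgoConfig",
    "GenerationSnapshot",
    "OptimisationResult",
    "Evaluator",
    "CountingEvaluator",
    "dominates",
    "nondominated_filter",
    "fast_nondominated_sort",
    "crowding_distance",
    "sbx_crossover",
    "polynomial_mutation",
    "random_genes",
    "clip_genes",
]

LOWER = np.array([CHROMOSOME_BOUNDS[g][0] for g in GENE_NAMES], dtype=np.float64)
UPPER = np.array([CHROMOSOME_BOUNDS[g][1] for g in GENE_NAMES], dtype=np.float64)
_INT_MASK = np.array([g in INTEGER_GENES for g in GENE_NAMES])

Evaluator = Callable[[Chromosome], ObjectiveVector]


@dataclass
class Individual:
    """One candidate solution plus algorithm-specific bookkeeping."""

    genes: np.ndarray
    objectives: np.ndarray | None = None
    rank: int = 0
    crowding: float = 0.0
    fitness: float = 0.0  # SPEA2 strength fitness (lower is better)
    velocity: np.ndarray | None = None  # PSO only
    pbest_genes: np.ndarray | None = None
    pbest_objectives: np.ndarray | None = None

    def copy(self) -> "Individual":
        return Individual(
            genes=self.genes.copy(),
            objectives=None if self.objectives is None else self.objectives.copy(),
            rank=self.rank,
            crowding=self.crowding,
            fitness=self.fitness,
            velocity=None if self.velocity is None else self.velocity.copy(),
            pbest_genes=None if self.pbest_genes is None else self.pbest_genes.copy(),
            pbest_objectives=(
                None if self.pbest_objectives is None else self.pbest_objectives.copy()
            ),
        )


@dataclass(frozen=True)
class AlgoConfig:
    """Hyperparameters shared by all five optimisers."""

    population_size: int = 40
    generations: int = 100
    crossover_prob: float = 0.40
    mutation_prob: float = 0.05
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    phi1: float = 2.05  # PSO
    phi2: float = 2.05  # PSO
    de_f: float = 1.0
    de_cr: float = 0.9
    archive_size: int | None = None  # defaults to population_size
    nsga3_divisions: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be at least 4")
        for p in (self.crossover_prob, self.mutation_prob, self.de_cr):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.archive_size is not None and self.archive_size < 1:
            raise ValueError("archive_size must be at least 1")

    @property
    def effective_archive_size(self) -> int:
        return self.archive_size if self.archive_size is not None else self.population_size


@dataclass(frozen=True)
class GenerationSnapshot:
    population_genes: np.ndarray  # (N, 6)
    population_objectives: np.ndarray  # (N, 4)
    archive_genes: np.ndarray | None = None
    archive_objectives: np.ndarray | None = None

    def front_objectives(self) -> np.ndarray:
        """Nondominated objective set of this generation (archive if kept)."""
        objs = (
            self.archive_objectives
            if self.archive_objectives is not None and len(self.archive_objectives)
            else self.population_objectives
        )
        return objs[nondominated_filter(objs)]


@dataclass
class OptimisationResult:
    algorithm: str
    config: AlgoConfig
    seed: int
    snapshots: list[GenerationSnapshot]
    final_front_genes: np.ndarray
    final_front_objectives: np.ndarray
    n_evaluations: int
    hv_trajectory: np.ndarray | None = None


class CountingEvaluator:
    """Wraps an evaluator, decodes gene arrays and counts evaluations."""

    def __init__(self, evaluator: Evaluator):
        self._evaluator = evaluator
        self.n_evaluations = 0

    def __call__(self, genes: np.ndarray) -> np.ndarray:
        chrom = clip_chromosome(genes)
        self.n_evaluations += 1
        return self._evaluator(chrom).as_array()

    def evaluate_all(self, pop: Sequence[Individual]) -> None:
        for ind in pop:
            if ind.objectives is None:
                ind.objectives = self(ind.genes)


def dominates(u: np.ndarray | ObjectiveVector, v: np.ndarray | ObjectiveVector) -> bool:
    """Pareto dominance for minimisation: u <= v everywhere, < somewhere."""
    if isinstance(u, ObjectiveVector):
        u = u.as_array()
    if isinstance(v, ObjectiveVector):
        v = v.as_array()
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    return bool(np.all(u <= v) and np.any(u < v))


def nondominated_filter(objectives: np.ndarray) -> np.ndarray:
    """Boolean mask of the mutually nondominated rows."""
    objs = np.asarray(objectives, dtype=np.float64)
    if objs.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    le = np.all(objs[:, None, :] <= objs[None, :, :], axis=2)
    lt = np.any(objs[:, None, :] < objs[None, :, :], axis=2)
    return ~(le & lt).any(axis=0)


def fast_nondominated_sort(objectives: np.ndarray) -> list[list[int]]:
    """Partition row indices into successive nondominated fronts."""
    objs = np.asarray(objectives, dtype=np.float64)
    if objs.ndim != 2:
        raise ValueError("objectives must be a 2-D array")
    if np.any(~np.isfinite(objs)):
        raise ValueError("all objectives must be set and finite before sorting")
    n = objs.shape[0]
    # pairwise dominance matrix: dom[i, j] = i dominates j
    le = np.all(objs[:, None, :] <= objs[None, :, :], axis=2)
    lt = np.any(objs[:, None, :] < objs[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    fronts: list[list[int]] = []
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.where((n_dominators == 0) & ~assigned)[0]
        if current.size == 0:  # pragma: no cover - cannot happen for finite input
            raise RuntimeError("nondominated sort failed to progress")
        fronts.append(current.tolist())
        assigned[current] = True
        n_dominators = n_dominators - dom[current].sum(axis=0)
    return fronts


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of each member of one front."""
    objs = np.asarray(objectives, dtype=np.float64)
    n, m = objs.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(objs[:, j], kind="stable")
        col = objs[order, j]
        span = col[-1] - col[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (col[2:] - col[:-2]) / span
    return dist


def random_genes(rng: np.random.Generator) -> np.ndarray:
    """Uniform gene vector inside the bounds (integer genes on the lattice)."""
    g = rng.uniform(LOWER, UPPER)
    g[_INT_MASK] = rng.integers(
        LOWER[_INT_MASK].astype(int), UPPER[_INT_MASK].astype(int) + 1
    ).astype(np.float64)
    return g


def clip_genes(genes: np.ndarray) -> np.ndarray:
    """Clip to bounds and round integer genes (continuous representation)."""
    g = np.clip(np.asarray(genes, dtype=np.float64), LOWER, UPPER)
    g[_INT_MASK] = np.clip(np.round(g[_INT_MASK]), LOWER[_INT_MASK], UPPER[_INT_MASK])
    return g


def sbx_crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    prob: float,
    eta: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover; with probability 1-prob parents pass through."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() >= prob:
        return c1, c2
    for j in range(p1.size):
        if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
            continue
        u = rng.random()
        if u <= 0.5:
            beta = (2.0 * u) ** (1.0 / (eta + 1.0))
        else:
            beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0))
        x1, x2 = min(p1[j], p2[j]), max(p1[j], p2[j])
        c1[j] = 0.5 * ((x1 + x2) - beta * (x2 - x1))
        c2[j] = 0.5 * ((x1 + x2) + beta * (x2 - x1))
    return clip_genes(c1), clip_genes(c2)


def polynomial_mutation(
    genes: np.ndarray, prob: float, eta: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene polynomial mutation within the bounds."""
    g = genes.copy()
    for j in range(g.size):
        if rng.random() >= prob:
            continue
        lo, hi = LOWER[j], UPPER[j]
        span = hi - lo
        u = rng.random()
        if u < 0.5:
            delta = (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0
        else:
            delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0))
        g[j] += delta * span
    return clip_genes(g)
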