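"""The five population-based multi-objective metaheuristics.

NSGA-II, SPEA2 and NSGA-III (genetic algorithms), an archive-guided particle
swarm (constriction form) and multi-objective DE/rand/1/bin with a
dominance-based replacement rule.  Each `*_generation` function advances one
generation; `run_algorithm` drives the common loop.
"""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

import numpy as np

from .core import (
    LOWER,
    UPPER,
    AlgoConfig,
    CountingEvaluator,
    Evaluator,
    GenerationSnapshot,
    Individual,
    OptimisationResult,
    crowding_distance,
    dominates,
    fast_nondominated_sort,
    nondominated_filter,
    polynomial_mutation,
    random_genes,
    sbx_crossover,
)

__all__ = [
    "de_trial",
    "nsga2_generation",
    "spea2_generation",
    "nsga3_reference_points",
    "nsga3_generation",
    "mopso_generation",
    "de_generation",
    "constriction_factor",
    "run_algorithm",
    "ALGORITHMS",
]


def _objs(pop: list[Individual]) -> np.ndarray:
    return np.array([ind.objectives for ind in pop])


def _assign_rank_crowding(pop: list[Individual]) -> None:
    fronts = fast_nondominated_sort(_objs(pop))
    for rank, front in enumerate(fronts):
        dists = crowding_distance(_objs([pop[i] for i in front]))
        for i, d in zip(front, dists):
            pop[i].rank = rank
            pop[i].crowding = float(d)


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    """Binary tournament on (rank asc, crowding desc)."""
    a, b = rng.integers(0, len(pop), size=2)
    ia, ib = pop[a], pop[b]
    if ia.rank != ib.rank:
        return ia if ia.rank < ib.rank else ib
    if ia.crowding != ib.crowding:
        return ia if ia.crowding > ib.crowding else ib
    return ia if rng.random() < 0.5 else ib


def _make_offspring(
    parents: list[Individual],
    n: int,
    cfg: AlgoConfig,
    rng: np.random.Generator,
    select,
) -> list[Individual]:
    children: list[Individual] = []
    while len(children) < n:
        p1, p2 = select(parents, rng), select(parents, rng)
        c1, c2 = sbx_crossover(p1.genes, p2.genes, cfg.crossover_prob, cfg.eta_crossover, rng)
        for c in (c1, c2):
            if len(children) < n:
                children.append(
                    Individual(polynomial_mutation(c, cfg.mutation_prob, cfg.eta_mutation, rng))
                )
    return children


def _truncate_by_rank_crowding(pop: list[Individual], n: int) -> list[Individual]:
    """Environmental selection: whole fronts first, crowding on the split front."""
    fronts = fast_nondominated_sort(_objs(pop))
    survivors: list[Individual] = []
    for rank, front in enumerate(fronts):
        members = [pop[i] for i in front]
        dists = crowding_distance(_objs(members))
        for ind, d in zip(members, dists):
            ind.rank = rank
            ind.crowding = float(d)
        if len(survivors) + len(members) <= n:
            survivors.extend(members)
        else:
            order = np.argsort(-dists, kind="stable")
            survivors.extend(members[i] for i in order[: n - len(survivors)])
            break
    return survivors


# ---------------------------------------------------------------------------
# NSGA-II


def nsga2_generation(
    pop: list[Individual],
    evaluator: CountingEvaluator,
    cfg: AlgoConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    _assign_rank_crowding(pop)
    offspring = _make_offspring(pop, cfg.population_size, cfg, rng, _tournament)
    evaluator.evaluate_all(offspring)
    return _truncate_by_rank_crowding(pop + offspring, cfg.population_size)


# ---------------------------------------------------------------------------
# SPEA2


def _spea2_fitness(union: list[Individual], k: int) -> np.ndarray:
    objs = _objs(union)
    n = len(union)
    le = np.all(objs[:, None, :] <= objs[None, :, :], axis=2)
    lt = np.any(objs[:, None, :] < objs[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    strength = dom.sum(axis=1).astype(np.float64)
    raw = np.array([strength[dom[:, i]].sum() for i in range(n)])
    dist = np.sqrt(((objs[:, None, :] - objs[None, :, :]) ** 2).sum(axis=2))
    sorted_dist = np.sort(dist, axis=1)
    k = min(k, n - 1)
    sigma_k = sorted_dist[:, k] if n > 1 else np.zeros(n)
    density = 1.0 / (sigma_k + 2.0)
    fitness = raw + density
    for ind, f in zip(union, fitness):
        ind.fitness = float(f)
    return fitness


def _spea2_truncate(archive: list[Individual], capacity: int) -> list[Individual]:
    """Iterative nearest-neighbour removal, protecting objective-wise extremes."""
    members = list(archive)
    while len(members) > capacity:
        objs = _objs(members)
        protected: set[int] = set()
        for j in range(objs.shape[1]):
            protected.add(int(np.argmin(objs[:, j])))
            protected.add(int(np.argmax(objs[:, j])))
        dist = np.sqrt(((objs[:, None, :] - objs[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        nn = dist.min(axis=1)
        candidates = [i for i in range(len(members)) if i not in protected]
        if not candidates:
            candidates = list(range(len(members)))
        drop = min(candidates, key=lambda i: (nn[i], i))
        members.pop(drop)
    return members


def _spea2_select(archive: list[Individual], rng: np.random.Generator) -> Individual:
    a, b = rng.integers(0, len(archive), size=2)
    ia, ib = archive[a], archive[b]
    if ia.fitness != ib.fitness:
        return ia if ia.fitness < ib.fitness else ib
    return ia if rng.random() < 0.5 else ib


def spea2_generation(
    pop: list[Individual],
    archive: list[Individual],
    evaluator: CountingEvaluator,
    cfg: AlgoConfig,
    rng: np.random.Generator,
) -> tuple[list[Individual], list[Individual]]:
    capacity = cfg.effective_archive_size
    union = pop + archive
    k = int(round(math.sqrt(cfg.population_size + capacity)))
    fitness = _spea2_fitness(union, k)
    nondom = [ind for ind, f in zip(union, fitness) if f < 1.0]
    if len(nondom) > capacity:
        new_archive = _spea2_truncate(nondom, capacity)
    else:
        new_archive = list(nondom)
        dominated = sorted(
            (ind for ind, f in zip(union, fitness) if f >= 1.0),
            key=lambda ind: ind.fitness,
        )
        new_archive.extend(dominated[: capacity - len(new_archive)])
    offspring = _make_offspring(new_archive, cfg.population_size, cfg, rng, _spea2_select)
    evaluator.evaluate_all(offspring)
    return offspring, new_archive


# ---------------------------------------------------------------------------
# NSGA-III


def nsga3_reference_points(n_objectives: int, divisions: int) -> np.ndarray:
    """Das-Dennis simplex-lattice points (each sums to 1)."""
    if divisions < 1:
        raise ValueError("divisions must be at least 1")
    points = []
    for combo in combinations_with_replacement(range(n_objectives), divisions):
        counts = np.bincount(np.asarray(combo), minlength=n_objectives)
        points.append(counts / divisions)
    return np.array(points)


def _associate(normalised: np.ndarray, refs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference line (perpendicular distance) per row."""
    unit = refs / np.linalg.norm(refs, axis=1, keepdims=True)
    proj = normalised @ unit.T  # (n, r) scalar projections
    dist2 = (normalised**2).sum(axis=1, keepdims=True) - proj**2
    dist2 = np.maximum(dist2, 0.0)
    nearest = np.argmin(dist2, axis=1)
    return nearest, np.sqrt(dist2[np.arange(len(normalised)), nearest])


def nsga3_generation(
    pop: list[Individual],
    evaluator: CountingEvaluator,
    cfg: AlgoConfig,
    rng: np.random.Generator,
    reference_points: np.ndarray,
) -> list[Individual]:
    n = cfg.population_size
    _assign_rank_crowding(pop)
    offspring = _make_offspring(pop, n, cfg, rng, _tournament)
    evaluator.evaluate_all(offspring)
    combined = pop + offspring
    fronts = fast_nondominated_sort(_objs(combined))

    selected: list[Individual] = []
    last_front: list[Individual] = []
    for front in fronts:
        members = [combined[i] for i in front]
        if len(selected) + len(members) <= n:
            selected.extend(members)
        else:
            last_front = members
            break
    if len(selected) == n or not last_front:
        return selected[:n]

    considered = selected + last_front
    objs = _objs(considered)
    ideal = objs.min(axis=0)
    nadir = objs.max(axis=0)
    span = np.where(nadir - ideal > 1e-12, nadir - ideal, 1.0)
    normalised = (objs - ideal) / span
    nearest, dist = _associate(normalised, reference_points)

    n_sel = len(selected)
    niche_count = np.bincount(nearest[:n_sel], minlength=len(reference_points))
    pending = {i: (nearest[n_sel + i], dist[n_sel + i]) for i in range(len(last_front))}
    while len(selected) < n and pending:
        active = {ref for ref, _ in pending.values()}
        min_count = min(niche_count[ref] for ref in active)
        candidates_refs = sorted(ref for ref in active if niche_count[ref] == min_count)
        ref = candidates_refs[rng.integers(0, len(candidates_refs))]
        members = [i for i, (r, _) in pending.items() if r == ref]
        if niche_count[ref] == 0:
            pick = min(members, key=lambda i: pending[i][1])
        else:
            pick = members[rng.integers(0, len(members))]
        selected.append(last_front[pick])
        del pending[pick]
        niche_count[ref] += 1
    return selected


# ---------------------------------------------------------------------------
# MOPSO


def constriction_factor(phi1: float, phi2: float) -> float:
    """Clerc-Kennedy constriction coefficient (phi = phi1 + phi2 > 4)."""
    phi = phi1 + phi2
    if phi <= 4.0:
        raise ValueError("constriction requires phi1 + phi2 > 4")
    return 2.0 / abs(2.0 - phi - math.sqrt(phi**2 - 4.0 * phi))


def _archive_insert(
    archive: list[Individual], candidates: list[Individual], capacity: int
) -> list[Individual]:
    """Merge, keep the nondominated set, truncate by lowest crowding first."""
    pool = archive + [c.copy() for c in candidates]
    objs = _objs(pool)
    # deduplicate identical objective vectors to keep the archive meaningful
    _, unique_idx = np.unique(objs.round(12), axis=0, return_index=True)
    pool = [pool[i] for i in sorted(unique_idx)]
    objs = _objs(pool)
    keep = nondominated_filter(objs)
    pool = [ind for ind, k in zip(pool, keep) if k]
    while len(pool) > capacity:
        dists = crowding_distance(_objs(pool))
        drop = int(np.argmin(dists))
        pool.pop(drop)
    for ind, d in zip(pool, crowding_distance(_objs(pool))):
        ind.crowding = float(d)
    return pool


def _leader(archive: list[Individual], rng: np.random.Generator) -> Individual:
    if len(archive) == 1:
        return archive[0]
    a, b = rng.integers(0, len(archive), size=2)
    ia, ib = archive[a], archive[b]
    if ia.crowding != ib.crowding:
        return ia if ia.crowding > ib.crowding else ib
    return ia if rng.random() < 0.5 else ib


def mopso_generation(
    swarm: list[Individual],
    archive: list[Individual],
    evaluator: CountingEvaluator,
    cfg: AlgoConfig,
    rng: np.random.Generator,
) -> tuple[list[Individual], list[Individual]]:
    chi = constriction_factor(cfg.phi1, cfg.phi2)
    if not archive:
        archive = _archive_insert([], swarm, cfg.effective_archive_size)
    for particle in swarm:
        leader = _leader(archive, rng)
        r1 = rng.random(particle.genes.size)
        r2 = rng.random(particle.genes.size)
        particle.velocity = chi * (
            particle.velocity
            + cfg.phi1 * r1 * (particle.pbest_genes - particle.genes)
            + cfg.phi2 * r2 * (leader.genes - particle.genes)
        )
        new_pos = particle.genes + particle.velocity
        clipped = np.clip(new_pos, LOWER, UPPER)
        particle.velocity[clipped != new_pos] = 0.0
        particle.genes = clipped
        particle.objectives = evaluator(particle.genes)
        if dominates(particle.objectives, particle.pbest_objectives):
            particle.pbest_genes = particle.genes.copy()
            particle.pbest_objectives = particle.objectives.copy()
        elif dominates(particle.pbest_objectives, particle.objectives):
            pass
        elif rng.random() < 0.5:
            particle.pbest_genes = particle.genes.copy()
            particle.pbest_objectives = particle.objectives.copy()
    archive = _archive_insert(archive, swarm, cfg.effective_archive_size)
    return swarm, archive


# ---------------------------------------------------------------------------
# Differential evolution (DE/rand/1/bin with dominance replacement)


def de_trial(
    genes: list[np.ndarray], i: int, f: float, cr: float, rng: np.random.Generator
) -> np.ndarray:
    """rand/1/bin trial vector for target i (one mutant gene guaranteed)."""
    choices = [j for j in range(len(genes)) if j != i]
    r1, r2, r3 = rng.choice(choices, size=3, replace=False)
    mutant = genes[r1] + f * (genes[r2] - genes[r3])
    trial = genes[i].copy()
    j_rand = rng.integers(0, trial.size)
    for j in range(trial.size):
        if rng.random() < cr or j == j_rand:
            trial[j] = mutant[j]
    return np.clip(trial, LOWER, UPPER)


def de_generation(
    pop: list[Individual],
    evaluator: CountingEvaluator,
    cfg: AlgoConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    n = cfg.population_size
    if len(pop) < 4:
        raise ValueError("DE needs a population of at least 4")
    base = [ind.copy() for ind in pop]
    pool = [ind.copy() for ind in pop]
    base_genes = [ind.genes for ind in base]
    for i in range(len(base)):
        trial = de_trial(base_genes, i, cfg.de_f, cfg.de_cr, rng)
        trial_ind = Individual(trial, evaluator(trial))
        if dominates(trial_ind.objectives, pool[i].objectives):
            pool[i] = trial_ind
        elif dominates(pool[i].objectives, trial_ind.objectives):
            continue
        else:
            pool.append(trial_ind)
    if len(pool) > n:
        pool = _truncate_by_rank_crowding(pool, n)
    return pool


# ---------------------------------------------------------------------------
# Driver

ALGORITHMS = ("nsga2", "spea2", "nsga3", "mopso", "de")
_ARCHIVE_BASED = {"spea2", "mopso"}


def run_algorithm(
    name: str,
    evaluator: Evaluator,
    cfg: AlgoConfig,
    seed: int | None = None,
) -> OptimisationResult:
    """Seeded full run of one metaheuristic; deterministic per (name, cfg, seed)."""
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; expected one of {ALGORITHMS}")
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    rng = np.random.default_rng(seed)
    counter = CountingEvaluator(evaluator)

    pop = [Individual(random_genes(rng)) for _ in range(cfg.population_size)]
    counter.evaluate_all(pop)
    if name == "mopso":
        for p in pop:
            p.velocity = np.zeros_like(p.genes)
            p.pbest_genes = p.genes.copy()
            p.pbest_objectives = p.objectives.copy()
    archive: list[Individual] = []
    if name in _ARCHIVE_BASED:
        from .core import nondominated_filter as _ndf

        keep = _ndf(_objs(pop))
        archive = [pop[i].copy() for i in range(len(pop)) if keep[i]]
    refs = nsga3_reference_points(4, cfg.nsga3_divisions) if name == "nsga3" else None

    def snapshot() -> GenerationSnapshot:
        return GenerationSnapshot(
            population_genes=np.array([p.genes for p in pop]),
            population_objectives=_objs(pop),
            archive_genes=np.array([a.genes for a in archive]) if archive else None,
            archive_objectives=_objs(archive) if archive else None,
        )

    snapshots = [snapshot()]
    for _ in range(cfg.generations):
        if name == "nsga2":
            pop = nsga2_generation(pop, counter, cfg, rng)
        elif name == "spea2":
            pop, archive = spea2_generation(pop, archive, counter, cfg, rng)
        elif name == "nsga3":
            pop = nsga3_generation(pop, counter, cfg, rng, refs)
        elif name == "mopso":
            pop, archive = mopso_generation(pop, archive, counter, cfg, rng)
        else:
            pop = de_generation(pop, counter, cfg, rng)
        snapshots.append(snapshot())

    final_pool = archive if archive else pop
    objs = _objs(final_pool)
    keep = nondominated_filter(objs)
    front = [final_pool[i] for i in range(len(final_pool)) if keep[i]]
    return OptimisationResult(
        algorithm=name,
        config=cfg,
        seed=seed,
        snapshots=snapshots,
        final_front_genes=np.array([f.genes for f in front]),
        final_front_objectives=_objs(front),
        n_evaluations=counter.n_evaluations,
    )
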