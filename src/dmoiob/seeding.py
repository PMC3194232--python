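"""Initial archive construction via a small NSGA-II run.

Starting the immune loop from an empty archive makes early guide
selection arbitrary; instead a compact NSGA-II (default 30 individuals,
10 generations; binary tournament, uniform crossover at rate 0.9,
per-bit flip mutation at rate 1/(n+m)) is run on random biclusters and
its final non-dominated front seeds the ε-archive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bicluster import Bicluster, objectives, random_bicluster, repair
from .matrix_io import ExpressionMatrix
from .pareto import Archive, crowding_distance, pareto_ranks
from .immune import Antibody


@dataclass
class SeedingConfig:
    population_size: int = 30
    generations: int = 10
    crossover_rate: float = 0.9
    min_genes: int = 2
    min_conditions: int = 2


def _rank_and_crowding(pop: list[Antibody]) -> tuple[np.ndarray, np.ndarray]:
    vectors = [a.objectives for a in pop]
    rank = pareto_ranks(vectors)
    crowd = np.zeros(len(pop))
    F = np.stack([v.values for v in vectors])
    for r in np.unique(rank):
        idx = np.flatnonzero(rank == r)
        crowd[idx] = crowding_distance(F[idx])
    return rank, crowd


def _tournament(rank, crowd, rng) -> int:
    i, j = rng.integers(0, len(rank), size=2)
    if rank[i] != rank[j]:
        return int(i if rank[i] < rank[j] else j)
    return int(i if crowd[i] >= crowd[j] else j)


def _uniform_crossover(a: Bicluster, b: Bicluster, rng) -> Bicluster:
    ga = np.concatenate([a.gene_mask, a.condition_mask])
    gb = np.concatenate([b.gene_mask, b.condition_mask])
    pick = rng.random(len(ga)) < 0.5
    child = np.where(pick, ga, gb)
    n = len(a.gene_mask)
    return Bicluster(child[:n], child[n:])


def _bitflip(B: Bicluster, rate: float, rng) -> Bicluster:
    bits = np.concatenate([B.gene_mask, B.condition_mask])
    flip = rng.random(len(bits)) < rate
    bits = bits ^ flip
    n = len(B.gene_mask)
    return Bicluster(bits[:n], bits[n:])


def seed_archive(
    M: ExpressionMatrix,
    delta: float,
    rng: np.random.Generator,
    epsilon=(0.02, 0.02, 0.02),
    capacity: int | None = 200,
    config: SeedingConfig = SeedingConfig(),
    history: list | None = None,
) -> Archive:
    """Run the seeding NSGA-II and return a fresh, non-empty ε-archive.

    ``history`` (if given) collects one population snapshot per
    generation, mainly so the generational structure is observable.
    """
    n, m = M.shape
    pop = [
        Antibody(b, objectives(M, b, delta))
        for b in (
            random_bicluster(
                n, m, rng,
                min_genes=config.min_genes,
                min_conditions=config.min_conditions,
            )
            for _ in range(config.population_size)
        )
    ]
    rate = 1.0 / (n + m)
    for _ in range(config.generations):
        rank, crowd = _rank_and_crowding(pop)
        children: list[Antibody] = []
        while len(children) < config.population_size:
            p1 = pop[_tournament(rank, crowd, rng)].bicluster
            p2 = pop[_tournament(rank, crowd, rng)].bicluster
            if rng.random() < config.crossover_rate:
                child = _uniform_crossover(p1, p2, rng)
            else:
                child = (p1 if rng.random() < 0.5 else p2).copy()
            child = _bitflip(child, rate, rng)
            child = repair(child, rng, config.min_genes, config.min_conditions)
            children.append(Antibody(child, objectives(M, child, delta)))
        combined = pop + children
        rank, crowd = _rank_and_crowding(combined)
        order = sorted(
            range(len(combined)), key=lambda i: (rank[i], -crowd[i])
        )
        pop = [combined[i] for i in order[: config.population_size]]
        if history is not None:
            history.append([a.bicluster.copy() for a in pop])

    archive = Archive(epsilon=np.asarray(epsilon, dtype=float), capacity=capacity)
    archive.refresh_bounds([a.objectives.values for a in pop])
    rank, _ = _rank_and_crowding(pop)
    for i in np.flatnonzero(rank == 0):
        archive.update(pop[i].bicluster, pop[i].objectives, tag=0)
    return archive
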