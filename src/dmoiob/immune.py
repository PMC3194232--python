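"""Clonal-selection operators and dynamic population sizing.

Antibodies (candidate biclusters) are cloned from the current
non-dominated set — the population's unconstrained Pareto front plus
the ε-archive members, whose boxes act as niches so that several
coherent submatrices can be pursued in parallel — and mutated, mostly
within a small Hamming neighbourhood of the parent (exploitation) and
occasionally further away (exploration).  Clone counts are adaptive:
δ-feasible candidates (those matching the target bicluster pattern)
receive the maximum clone count, the immune notion of affinity-
proportional expansion.

The population size breathes between ``n_min`` and ``n_max`` instead of
being fixed: clonal expansion grows it, an environmental truncation
enforces the ceiling, and a decreasing step prunes a small fraction of
antibodies each generation, chosen among those whose σ value sits
farthest from their best local guide — stragglers not tracking any
archive direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bicluster import Bicluster, ObjectiveVector, objectives, repair
from .errors import ParameterError
from .matrix_io import ExpressionMatrix
from .pareto import Archive, crowding_distance, nondominated_mask, pareto_ranks
from .sigma import guide_indices


@dataclass
class Antibody:
    bicluster: Bicluster
    objectives: ObjectiveVector


@dataclass
class MutationParams:
    """Neighbourhood structure of the clonal mutation operator.

    ``k_near``/``k_far`` bound the number of bit flips for near and far
    mutations; ``p_near`` is the probability of staying near; ``c_min``/
    ``c_max`` bound how many clones a selected antibody produces.
    """

    c_min: int = 1
    c_max: int = 10
    p_near: float = 0.9
    k_near: int = 1
    k_far: int = 2
    min_genes: int = 2
    min_conditions: int = 2

    @classmethod
    def for_string_length(cls, total_bits: int, **overrides) -> "MutationParams":
        """Scale flip counts to the encoding length: near mutations touch
        ~1% of the bits, far mutations up to ~5%."""
        k_near = max(1, round(0.01 * total_bits))
        k_far = max(k_near + 1, round(0.05 * total_bits))
        params = {"k_near": k_near, "k_far": k_far, **overrides}
        return cls(**params)


@dataclass
class Population:
    """The dynamically sized antibody set evolved each generation."""

    antibodies: list[Antibody]
    n_min: int = 20
    n_max: int = 300
    generation: int = 0

    def __len__(self) -> int:
        return len(self.antibodies)

    def objective_vectors(self) -> list[ObjectiveVector]:
        return [a.objectives for a in self.antibodies]

    def nondominated(self, constrained: bool = False) -> list[Antibody]:
        mask = nondominated_mask(self.objective_vectors(), constrained=constrained)
        return [a for a, keep in zip(self.antibodies, mask) if keep]


def mutate(
    B: Bicluster,
    near: bool,
    rng: np.random.Generator,
    params: MutationParams = MutationParams(),
) -> Bicluster:
    """Flip k random bits of the encoding (k ~ U{1..k_near} near, or
    U{k_near+1..k_far} far), then repair to the minimum bicluster size."""
    n = len(B.gene_mask)
    m = len(B.condition_mask)
    if near:
        k = int(rng.integers(1, params.k_near + 1))
    else:
        k = int(rng.integers(params.k_near + 1, params.k_far + 1))
    k = min(k, n + m)
    bits = np.concatenate([B.gene_mask, B.condition_mask])
    flip = rng.choice(n + m, size=k, replace=False)
    bits[flip] = ~bits[flip]
    child = Bicluster(bits[:n], bits[n:])
    return repair(child, rng, params.min_genes, params.min_conditions)


def select_clone_candidates(
    nd_set: list,
    rng: np.random.Generator,
    r1: float | None = None,
) -> list:
    """Sample ns = floor(r1·|ND|) members without replacement from the
    non-dominated set, r1 ~ U[0, 1] (or forced for testing)."""
    if r1 is None:
        r1 = float(rng.random())
    ns = int(math.floor(r1 * len(nd_set)))
    if ns == 0:
        return []
    idx = rng.choice(len(nd_set), size=ns, replace=False)
    return [nd_set[i] for i in idx]


def clone_pool(P: Population, A: Archive) -> list[tuple[Bicluster, ObjectiveVector]]:
    """The non-dominated candidate set offered to clonal selection:
    population Pareto front ∪ archive members, deduplicated by mask."""
    pool: dict[bytes, tuple[Bicluster, ObjectiveVector]] = {}
    for a in P.nondominated(constrained=False):
        pool.setdefault(a.bicluster.key(), (a.bicluster, a.objectives))
    for m in A.members:
        pool.setdefault(m.bicluster.key(), (m.bicluster, m.objectives))
    return list(pool.values())


def _clone_count(f: ObjectiveVector, params: MutationParams, rng) -> int:
    """Affinity-adaptive clone count: δ-feasible parents expand maximally,
    infeasible parents draw uniformly from [c_min, c_max]."""
    if f.feasible:
        return params.c_max
    span = params.c_max - params.c_min + 1
    return params.c_min + min(int(math.floor(rng.random() * span)), span - 1)


def population_add(
    P: Population,
    A: Archive,
    M: ExpressionMatrix,
    delta: float,
    rng: np.random.Generator,
    params: MutationParams = MutationParams(),
    r1: float | None = None,
    tag: int = 0,
) -> Population:
    """Grow the population by clonal expansion of the non-dominated set.

    Each clone candidate spawns c new antibodies, each a near mutation
    with probability ``p_near``; every clone is evaluated and offered to
    the archive.  The ``n_max`` ceiling is enforced by environmental
    truncation of parents ∪ clones so the population keeps turning over
    instead of freezing once the ceiling is reached.
    """
    candidates = select_clone_candidates(clone_pool(P, A), rng, r1=r1)
    new: list[Antibody] = []
    for parent_b, parent_f in candidates:
        c = _clone_count(parent_f, params, rng)
        for _ in range(c):
            near = bool(rng.random() < params.p_near)
            child = mutate(parent_b, near, rng, params)
            f = objectives(M, child, delta)
            A.update(child, f, tag=tag)
            new.append(Antibody(child, f))
    combined = P.antibodies + new
    if len(combined) > P.n_max:
        combined = truncate_population(combined, P.n_max)
    return Population(combined, P.n_min, P.n_max, P.generation)


def truncate_population(
    antibodies: list[Antibody], n_max: int, feasible_share: float = 0.7
) -> list[Antibody]:
    """Two-class environmental truncation to at most ``n_max`` antibodies.

    Duplicates (identical masks) are merged first.  The δ-feasible class
    — the memory repertoire carrying volume growth — is kept by (Pareto
    rank, volume descending) up to ~``feasible_share`` of the ceiling;
    the infeasible class — the naive repertoire still descending toward
    the δ region — fills the rest by (unconstrained rank, crowding).
    Volume rather than crowding breaks feasible ties because growth
    relies on retaining several near-frontier members of each coherent
    submatrix, exactly the dense clusters crowding would thin out.
    """
    unique: dict[bytes, Antibody] = {}
    for a in antibodies:
        unique.setdefault(a.bicluster.key(), a)
    pool = list(unique.values())
    if len(pool) <= n_max:
        return pool

    feas = [a for a in pool if a.objectives.feasible]
    infeas = [a for a in pool if not a.objectives.feasible]
    cap_f = min(len(feas), max(int(feasible_share * n_max), n_max - len(infeas)))
    if len(feas) > cap_f:
        rank = pareto_ranks([a.objectives for a in feas], constrained=False)
        order = sorted(
            range(len(feas)), key=lambda i: (rank[i], -feas[i].objectives.volume)
        )
        feas = [feas[i] for i in order[:cap_f]]
    cap_i = n_max - len(feas)
    if len(infeas) > cap_i:
        rank = pareto_ranks([a.objectives for a in infeas], constrained=False)
        crowd = np.zeros(len(infeas))
        F = np.stack([a.objectives.values for a in infeas])
        for r in np.unique(rank):
            idx = np.flatnonzero(rank == r)
            crowd[idx] = crowding_distance(F[idx])
        order = sorted(range(len(infeas)), key=lambda i: (rank[i], -crowd[i]))
        infeas = [infeas[i] for i in order[:cap_i]]
    return feas + infeas


def population_decrease(
    P: Population,
    A: Archive,
    S: float,
    rng: np.random.Generator,
) -> Population:
    """Remove round(S·|P|) antibodies, biased toward σ-stragglers.

    Antibodies are ranked by the σ-distance to their best local guide;
    removal is a weighted draw (weight 1/rank) restricted to the ~20%
    farthest from any archive direction, and never takes |P| below
    ``n_min``.
    """
    if not 0.0 <= S <= 1.0:
        raise ParameterError(f"selection ratio must lie in [0, 1], got {S}")
    k = int(math.floor(S * len(P) + 0.5))  # round half up, deterministic
    k = min(k, len(P) - P.n_min)
    if k <= 0 or not P.antibodies:
        return P
    F = np.stack([a.objectives.values for a in P.antibodies])
    _, dist = guide_indices(F, A)
    order = np.argsort(-dist, kind="stable")  # farthest first
    pool = order[: max(k, math.ceil(0.2 * len(P)))]
    weights = 1.0 / np.arange(1, len(pool) + 1)
    removed = rng.choice(pool, size=k, replace=False, p=weights / weights.sum())
    keep = np.setdiff1d(np.arange(len(P)), removed)
    return Population([P.antibodies[i] for i in keep], P.n_min, P.n_max, P.generation)
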