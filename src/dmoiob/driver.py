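"""The main optimization loop: seed, evolve, harvest.

Each generation the current population is offered to the ε-archive
(after refreshing the archive's normalization bounds over archive ∪
population), the non-dominated set (population front ∪ archive) is
clonally expanded with neighbourhood-biased mutation, and a small
fraction of σ-straggler antibodies is pruned, so the population size
floats between its bounds.  After a fixed number of generations the
feasible (MSR ≤ δ) archive members are reported, largest volume first.

The initial population is built from gene-pair probes — two random
genes across roughly half the conditions — plus a few minimal random
biclusters.  A probe whose two genes are co-expressed is a handful of
condition deletions away from a δ-bicluster, which is what lets the
clonal search localize coherent submatrices in an otherwise
unstructured matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .bicluster import Bicluster, objectives
from .errors import ParameterError
from .matrix_io import ExpressionMatrix
from .immune import (
    Antibody,
    MutationParams,
    Population,
    population_add,
    population_decrease,
)
from .pareto import Archive, hypervolume, log_compress
from .seeding import SeedingConfig, seed_archive

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of one optimization run.

    ``delta`` is the MSR feasibility threshold in squared expression
    units (300 for yeast-scale data, 1200 for human-B-cell-scale data);
    ``epsilon`` are the per-objective box widths on [0, 1]-normalized
    objectives; ``S`` is the fraction of the population pruned per
    generation.  ``k_near``/``k_far`` default to ~1% / ~5% of the
    encoding length when left unset.
    """

    delta: float = 300.0
    epsilon: tuple[float, float, float] = (0.02, 0.02, 0.02)
    generations: int = 100
    n_min: int = 20
    n_max: int = 300
    initial_size: int = 50
    S: float = 0.02
    c_min: int = 1
    c_max: int = 10
    p_near: float = 0.9
    k_near: int | None = None
    k_far: int | None = None
    min_genes: int = 2
    min_conditions: int = 2
    impute_low: float = 0.0
    impute_high: float = 800.0
    archive_capacity: int | None = 200
    seed_population: int = 30
    seed_generations: int = 10
    top_k: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.delta <= 0:
            raise ParameterError("delta must be positive")
        if not 0.0 <= self.S <= 0.2:
            raise ParameterError("selection ratio S must lie in [0, 0.2]")
        for name in ("generations",):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("n_min", "n_max", "initial_size", "c_min", "c_max",
                     "min_genes", "min_conditions", "top_k"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_min > self.n_max:
            raise ParameterError("n_min must not exceed n_max")
        if any(e <= 0 for e in self.epsilon):
            raise ParameterError("epsilon components must be positive")

    def mutation_params(self, n: int, m: int) -> MutationParams:
        overrides = {}
        if self.k_near is not None:
            overrides["k_near"] = self.k_near
        if self.k_far is not None:
            overrides["k_far"] = self.k_far
        return MutationParams.for_string_length(
            n + m,
            c_min=self.c_min,
            c_max=self.c_max,
            p_near=self.p_near,
            min_genes=self.min_genes,
            min_conditions=self.min_conditions,
            **overrides,
        )


@dataclass
class BiclusterResult:
    """One reported δ-bicluster."""

    bicluster: Bicluster
    msr: float
    row_variance: float
    volume: int
    generation_found: int

    def to_dict(self, M: ExpressionMatrix | None = None) -> dict:
        d = {
            "msr": self.msr,
            "row_variance": self.row_variance,
            "volume": self.volume,
            "generation_found": self.generation_found,
        }
        if M is not None:
            d["genes"] = [g for g, keep in zip(M.gene_ids, self.bicluster.gene_mask) if keep]
            d["conditions"] = [
                c for c, keep in zip(M.condition_ids, self.bicluster.condition_mask) if keep
            ]
        else:
            d["gene_bits"] = self.bicluster.encode()
        return d


@dataclass
class RunHistory:
    """Per-generation trace of the dynamic-size behaviour."""

    population_size: list[int] = field(default_factory=list)
    archive_size: list[int] = field(default_factory=list)
    best_msr: list[float] = field(default_factory=list)
    max_volume: list[float] = field(default_factory=list)
    hypervolume: list[float] = field(default_factory=list)


def probe_bicluster(
    n: int,
    m: int,
    rng: np.random.Generator,
    n_genes: int = 2,
    condition_p: float = 0.5,
    min_conditions: int = 2,
) -> Bicluster:
    """A gene-pair probe: ``n_genes`` random genes over ~``condition_p``
    of the conditions — the canonical starting point for localizing a
    pair of co-expressed genes."""
    g = np.zeros(n, dtype=bool)
    g[rng.choice(n, size=n_genes, replace=False)] = True
    c = rng.random(m) < condition_p
    if c.sum() < min_conditions:
        c[rng.choice(m, size=min_conditions, replace=False)] = True
    return Bicluster(g, c)


def initial_population(
    M: ExpressionMatrix, cfg: "RunConfig", rng: np.random.Generator
) -> Population:
    """Mixed initial repertoire: 4/5 gene-pair probes, 1/5 minimal
    (min_genes × min_conditions) random biclusters."""
    n, m = M.shape
    antibodies = []
    for i in range(cfg.initial_size):
        if i % 5 < 4:
            b = probe_bicluster(
                n, m, rng,
                n_genes=max(2, cfg.min_genes),
                min_conditions=cfg.min_conditions,
            )
        else:
            g = np.zeros(n, dtype=bool)
            c = np.zeros(m, dtype=bool)
            g[rng.choice(n, size=cfg.min_genes, replace=False)] = True
            c[rng.choice(m, size=cfg.min_conditions, replace=False)] = True
            b = Bicluster(g, c)
        antibodies.append(Antibody(b, objectives(M, b, cfg.delta)))
    return Population(antibodies, n_min=cfg.n_min, n_max=cfg.n_max)


def _hv_bounds(M: ExpressionMatrix, cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fixed log-scale normalization bounds for hypervolume tracking
    (the archive's own ε-boxes use adaptive bounds instead)."""
    n, m = M.shape
    full = Bicluster(np.ones(n, bool), np.ones(m, bool))
    f_full = objectives(M, full, cfg.delta)
    msr_hi = max(cfg.delta, f_full.msr)
    rv_hi = max(f_full.row_variance, 1.0)
    lo = log_compress(np.array([0.0, -4.0 * n * m, -16.0 * rv_hi]))
    hi = log_compress(np.array([16.0 * msr_hi, 0.0, 0.0]))
    return lo, hi


def _archive_hypervolume(A: Archive, lo: np.ndarray, hi: np.ndarray) -> float:
    span = np.where(hi > lo, hi - lo, 1.0)
    pts = np.stack([log_compress(v) for v in A.objective_matrix()])
    pts = np.clip((pts - lo) / span, 0.0, 1.0)
    return hypervolume(pts, ref=(1.0, 1.0, 1.0))


def run(
    M: ExpressionMatrix,
    cfg: RunConfig,
    history: RunHistory | None = None,
) -> list[BiclusterResult]:
    """Execute the full algorithm and return up to ``cfg.top_k`` feasible
    biclusters ranked by volume (descending), ties by lower MSR."""
    cfg.validate()
    if np.isnan(M.values).any():
        raise ParameterError("matrix contains unimputed missing values")
    n, m = M.shape
    rng = np.random.default_rng(cfg.seed)
    params = cfg.mutation_params(n, m)

    archive = seed_archive(
        M,
        cfg.delta,
        rng,
        epsilon=cfg.epsilon,
        capacity=cfg.archive_capacity,
        config=SeedingConfig(
            population_size=cfg.seed_population,
            generations=cfg.seed_generations,
            min_genes=cfg.min_genes,
            min_conditions=cfg.min_conditions,
        ),
    )

    pop = initial_population(M, cfg, rng)
    hv_lo, hv_hi = _hv_bounds(M, cfg)

    for t in range(1, cfg.generations + 1):
        pop.generation = t
        archive.refresh_bounds(a.objectives.values for a in pop.antibodies)
        for ab in pop.antibodies:
            archive.update(ab.bicluster, ab.objectives, tag=t)
        pop = population_add(pop, archive, M, cfg.delta, rng, params, tag=t)
        pop = population_decrease(pop, archive, cfg.S, rng)

        if history is not None or logger.isEnabledFor(logging.INFO):
            feas = archive.feasible_members()
            best_msr = min((mm.objectives.msr for mm in archive.members), default=np.nan)
            max_vol = max((mm.objectives.volume for mm in feas), default=0.0)
            hv = _archive_hypervolume(archive, hv_lo, hv_hi)
            g_cov, c_cov, cell_cov = coverage(
                [mm.bicluster for mm in feas], n, m
            )
            logger.info(
                "gen %d: |P|=%d |A|=%d best_msr=%.3f max_feasible_volume=%d "
                "hv=%.4f archive coverage: genes %.1f%% conds %.1f%% cells %.1f%%",
                t, len(pop), len(archive), best_msr, int(max_vol), hv,
                g_cov, c_cov, cell_cov,
            )
            if history is not None:
                history.population_size.append(len(pop))
                history.archive_size.append(len(archive))
                history.best_msr.append(float(best_msr))
                history.max_volume.append(float(max_vol))
                history.hypervolume.append(hv)

    results = harvest(archive, cfg.top_k)
    if not results:
        logger.warning("no feasible bicluster (MSR <= %.4g) was found", cfg.delta)
    return results


def harvest(archive: Archive, top_k: int) -> list[BiclusterResult]:
    """Feasible archive members, deduplicated, largest volume first."""
    seen: set[bytes] = set()
    results: list[BiclusterResult] = []
    for mem in archive.feasible_members():
        key = mem.bicluster.key()
        if key in seen:
            continue
        seen.add(key)
        f = mem.objectives
        results.append(
            BiclusterResult(
                bicluster=mem.bicluster,
                msr=f.msr,
                row_variance=f.row_variance,
                volume=int(f.volume),
                generation_found=mem.tag,
            )
        )
    results.sort(key=lambda r: (-r.volume, r.msr))
    return results[:top_k]


def coverage(
    results: list[BiclusterResult],
    n: int,
    m: int,
) -> tuple[float, float, float]:
    """Percentage of genes, conditions and cells covered by the union of
    the reported biclusters."""
    genes = np.zeros(n, dtype=bool)
    conds = np.zeros(m, dtype=bool)
    cells = np.zeros((n, m), dtype=bool)
    for r in results:
        b = getattr(r, "bicluster", r)
        genes |= b.gene_mask
        conds |= b.condition_mask
        cells |= np.outer(b.gene_mask, b.condition_mask)
    return (
        100.0 * genes.sum() / n,
        100.0 * conds.sum() / m,
        100.0 * cells.sum() / (n * m),
    )


def results_to_json(results: list[BiclusterResult], M: ExpressionMatrix) -> str:
    return json.dumps([r.to_dict(M) for r in results], indent=1)


def results_to_text(results: list[BiclusterResult], M: ExpressionMatrix) -> str:
    """Classic two-line-per-bicluster interchange format: a gene-list
    line followed by a condition-list line."""
    lines = []
    for r in results:
        lines.append(" ".join(
            g for g, keep in zip(M.gene_ids, r.bicluster.gene_mask) if keep))
        lines.append(" ".join(
            c for c, keep in zip(M.condition_ids, r.bicluster.condition_mask) if keep))
    return "\n".join(lines) + ("\n" if lines else "")
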