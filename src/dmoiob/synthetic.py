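"""Synthetic expression matrices with planted biclusters.

The generator emulates the two compendia the method targets — a
yeast-cell-cycle-like matrix (integer-scale values on 0–600) and a
human-B-cell-like matrix (values on −750–650 with ~12% missing
entries) — by drawing background cells uniformly on the data range and
overwriting planted submatrices with a constant or additive model
d_ij = μ + α_i + β_j plus Gaussian noise.  A noiseless additive plant
has mean squared residue exactly 0 on its own cells, so recovery is
well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bicluster import Bicluster
from .errors import ParameterError
from .matrix_io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: data ranges of the two emulated compendia
YEAST_RANGE = (0.0, 600.0)
HUMAN_RANGE = (-750.0, 650.0)


@dataclass
class PlantedBicluster:
    """One planted submatrix.

    ``model`` is ``"constant"`` (every cell μ) or ``"additive"``
    (d_ij = μ + α_i + β_j with row/column effects drawn uniformly on
    ±``effect_scale``·(background range)).  ``noise_sd`` is the SD of
    additive Gaussian noise on the plant's cells, in expression units.
    """

    gene_indices: np.ndarray
    condition_indices: np.ndarray
    model: str = "additive"
    noise_sd: float = 0.0
    mean: float | None = None  # default: background midpoint
    effect_scale: float = 0.2

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=int)
        self.condition_indices = np.asarray(self.condition_indices, dtype=int)
        if self.model not in ("constant", "additive"):
            raise ParameterError(f"unknown plant model {self.model!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    def mask(self, n: int, m: int) -> Bicluster:
        g = np.zeros(n, dtype=bool)
        c = np.zeros(m, dtype=bool)
        g[self.gene_indices] = True
        c[self.condition_indices] = True
        return Bicluster(g, c)


def generate(
    n: int,
    m: int,
    plants: list[PlantedBicluster],
    background: tuple[float, float] = YEAST_RANGE,
    missing_frac: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> tuple[ExpressionMatrix, list[Bicluster]]:
    """Build an n×m matrix with the given plants; return it with the
    ground-truth masks (one per plant, in order)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    low, high = background
    if not low < high:
        raise ParameterError("background bounds must satisfy low < high")
    if not 0.0 <= missing_frac < 1.0:
        raise ParameterError("missing_frac must lie in [0, 1)")

    values = rng.uniform(low, high, size=(n, m))
    occupied = np.zeros((n, m), dtype=bool)
    truth: list[Bicluster] = []
    for plant in plants:
        gi, ci = plant.gene_indices, plant.condition_indices
        if gi.size == 0 or ci.size == 0:
            raise ParameterError("plant must select at least one gene and condition")
        if gi.min() < 0 or gi.max() >= n or ci.min() < 0 or ci.max() >= m:
            raise ParameterError("plant indices exceed matrix bounds")
        cells = np.ix_(gi, ci)
        if occupied[cells].any():
            logger.warning("planted biclusters overlap; later plant overwrites")
        occupied[cells] = True

        mu = plant.mean if plant.mean is not None else (low + high) / 2.0
        if plant.model == "constant":
            block = np.full((gi.size, ci.size), mu)
        else:
            amp = plant.effect_scale * (high - low)
            alpha = rng.uniform(-amp, amp, size=gi.size)
            beta = rng.uniform(-amp, amp, size=ci.size)
            block = mu + alpha[:, None] + beta[None, :]
        if plant.noise_sd > 0:
            block = block + rng.normal(0.0, plant.noise_sd, size=block.shape)
        values[cells] = block
        truth.append(plant.mask(n, m))

    mask = np.zeros((n, m), dtype=bool)
    k = int(round(missing_frac * n * m))
    if k:
        flat = rng.choice(n * m, size=k, replace=False)
        mask.flat[flat] = True
        values[mask] = np.nan

    M = ExpressionMatrix(
        values,
        [f"g{i + 1}" for i in range(n)],
        [f"c{j + 1}" for j in range(m)],
        mask,
    )
    return M, truth


def benchmark(
    n: int = 200,
    m: int = 40,
    gene_counts: tuple[int, ...] = (50, 45, 40),
    condition_counts: tuple[int, ...] = (28, 26, 24),
    noise_sd: float = 10.0,
    background: tuple[float, float] = YEAST_RANGE,
    missing_frac: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> tuple[ExpressionMatrix, list[Bicluster]]:
    """The package's standard recovery benchmark: a yeast-like matrix
    with non-overlapping additive plants.

    Plant geometry mirrors the biclusters reported on the yeast
    compendium scaled to the matrix: gene sets are disjoint (so plants
    never share cells) and jointly cover ~2/3 of the genes, while each
    plant spans most of the conditions, the way real cell-cycle
    biclusters span most time points.  ``noise_sd`` defaults to 10
    expression units, i.e. plant MSR ≈ 100, comfortably inside the
    yeast-scale threshold δ = 300.
    """
    if len(gene_counts) != len(condition_counts):
        raise ParameterError("gene_counts and condition_counts differ in length")
    if sum(gene_counts) > n:
        raise ParameterError("plants need disjoint gene sets that fit the matrix")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    gene_pool = rng.permutation(n)
    plants, start = [], 0
    for ng, nc in zip(gene_counts, condition_counts):
        gi = np.sort(gene_pool[start:start + ng])
        start += ng
        ci = np.sort(rng.choice(m, size=nc, replace=False))
        plants.append(
            PlantedBicluster(gi, ci, model="additive", noise_sd=noise_sd)
        )
    return generate(n, m, plants, background=background,
                    missing_frac=missing_frac, rng=rng)


def _cells(b: Bicluster) -> np.ndarray:
    return np.outer(b.gene_mask, b.condition_mask)


def cell_jaccard(a: Bicluster, b: Bicluster) -> float:
    """Jaccard index of the two biclusters' cell sets."""
    ca, cb = _cells(a), _cells(b)
    union = int(np.logical_or(ca, cb).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(ca, cb).sum() / union)


def recovery_score(found, truth: list[Bicluster]) -> float:
    """Mean over planted biclusters of the best cell-set Jaccard index
    against any found bicluster (0 = nothing recovered, 1 = exact)."""
    if not truth:
        raise ParameterError("no planted biclusters to score against")
    found_masks = [getattr(f, "bicluster", f) for f in found]
    scores = []
    for t in truth:
        best = max((cell_jaccard(f, t) for f in found_masks), default=0.0)
        scores.append(best)
    return float(np.mean(scores))
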