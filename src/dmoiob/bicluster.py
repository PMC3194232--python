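"""Bicluster encoding and the three optimization objectives.

A bicluster is a pair of boolean masks over the genes and conditions of
an expression matrix, interchangeable with a fixed-length binary string:
the first n bits select genes, the remaining m bits select conditions,
optionally separated by ``#`` in the textual form.

Three quantities drive the search, all posed for minimization:

* mean squared residue (MSR) — the Cheng–Church homogeneity score, the
  mean of r_ij² over the submatrix with residue
  r_ij = d_ij − d_iJ − d_Ij + d_IJ (row, column and overall submatrix
  means).  MSR is zero exactly for additive submatrices and a bicluster
  is called feasible (a δ-bicluster) when MSR ≤ δ.
* volume — the cell count |genes|·|conditions|, negated so larger
  biclusters score lower.
* row variance — mean of (d_ij − d_iJ)² over selected cells, negated;
  it penalises trivially flat biclusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EncodingError, ParameterError
from .matrix_io import ExpressionMatrix

SEPARATOR = "#"


@dataclass
class Bicluster:
    """Gene/condition selection masks over an n×m matrix."""

    gene_mask: np.ndarray
    condition_mask: np.ndarray

    def __post_init__(self) -> None:
        self.gene_mask = np.asarray(self.gene_mask, dtype=bool)
        self.condition_mask = np.asarray(self.condition_mask, dtype=bool)

    @property
    def n_genes(self) -> int:
        return int(self.gene_mask.sum())

    @property
    def n_conditions(self) -> int:
        return int(self.condition_mask.sum())

    @property
    def volume(self) -> int:
        return self.n_genes * self.n_conditions

    def key(self) -> bytes:
        """Hashable identity of the (gene-mask, condition-mask) pair."""
        return np.packbits(np.concatenate([self.gene_mask, self.condition_mask])).tobytes()

    def copy(self) -> "Bicluster":
        return Bicluster(self.gene_mask.copy(), self.condition_mask.copy())

    def encode(self, separator: str = SEPARATOR) -> str:
        bits = lambda mask: "".join("1" if b else "0" for b in mask)
        return bits(self.gene_mask) + separator + bits(self.condition_mask)

    @classmethod
    def decode(cls, s: str, n: int, m: int) -> "Bicluster":
        """Decode a binary string of length n+m (``#`` delimiter optional)."""
        raw = s.replace(SEPARATOR, "")
        if len(raw) != n + m:
            raise EncodingError(
                f"expected {n}+{m}={n + m} bits, got {len(raw)}"
            )
        if set(raw) - {"0", "1"}:
            raise EncodingError(f"non-binary characters in {s!r}")
        bits = np.frombuffer(raw.encode(), dtype=np.uint8) - ord("0")
        return cls(bits[:n].astype(bool), bits[n:].astype(bool))


def decode(s: str, n: int, m: int) -> Bicluster:
    return Bicluster.decode(s, n, m)


def volume(B: Bicluster) -> int:
    return B.volume


def _submatrix(M: ExpressionMatrix, B: Bicluster) -> np.ndarray:
    if B.n_genes == 0 or B.n_conditions == 0:
        raise DomainError("bicluster selects no genes or no conditions")
    return M.values[np.ix_(B.gene_mask, B.condition_mask)]


def msr(M: ExpressionMatrix, B: Bicluster) -> float:
    """Mean squared residue of the selected submatrix (Cheng–Church)."""
    sub = _submatrix(M, B)
    row_means = sub.mean(axis=1, keepdims=True)
    col_means = sub.mean(axis=0, keepdims=True)
    resid = sub - row_means - col_means + sub.mean()
    return float(np.mean(resid * resid))


def row_variance(M: ExpressionMatrix, B: Bicluster) -> float:
    """Mean squared deviation of selected cells from their row means."""
    sub = _submatrix(M, B)
    dev = sub - sub.mean(axis=1, keepdims=True)
    return float(np.mean(dev * dev))


@dataclass
class ObjectiveVector:
    """Minimization triple (MSR, −volume, −row variance) with a δ flag."""

    values: np.ndarray  # shape (3,)
    feasible: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3,):
            raise ParameterError("objective vector must have 3 components")

    @property
    def msr(self) -> float:
        return float(self.values[0])

    @property
    def volume(self) -> float:
        return -float(self.values[1])

    @property
    def row_variance(self) -> float:
        return -float(self.values[2])


def objectives(M: ExpressionMatrix, B: Bicluster, delta: float) -> ObjectiveVector:
    """Evaluate the minimization triple and the MSR ≤ δ feasibility flag."""
    if delta <= 0:
        raise ParameterError(f"delta must be positive, got {delta}")
    h = msr(M, B)
    return ObjectiveVector(
        np.array([h, -float(B.volume), -row_variance(M, B)]),
        feasible=h <= delta,
    )


def repair(
    B: Bicluster,
    rng: np.random.Generator,
    min_genes: int = 2,
    min_conditions: int = 2,
) -> Bicluster:
    """Randomly switch on bits until the minimum-size invariant holds."""
    out = B.copy()
    for mask, lo in ((out.gene_mask, min_genes), (out.condition_mask, min_conditions)):
        deficit = lo - int(mask.sum())
        if deficit > 0:
            off = np.flatnonzero(~mask)
            mask[rng.choice(off, size=deficit, replace=False)] = True
    return out


def random_bicluster(
    n: int,
    m: int,
    rng: np.random.Generator,
    gene_p: float | None = None,
    condition_p: float = 0.5,
    min_genes: int = 2,
    min_conditions: int = 2,
) -> Bicluster:
    """Sample a small random bicluster (each gene bit on with probability
    ~10/n, each condition bit with probability 0.5), repaired to the
    minimum size."""
    if gene_p is None:
        gene_p = min(1.0, 10.0 / n)
    B = Bicluster(rng.random(n) < gene_p, rng.random(m) < condition_p)
    return repair(B, rng, min_genes, min_conditions)
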