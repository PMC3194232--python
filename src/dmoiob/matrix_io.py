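"""Reading, writing and imputation of gene-expression matrices.

A matrix file is a tab- or whitespace-delimited table of real numbers,
genes in rows and conditions in columns.  Two dialects are accepted:

* labeled  — first row holds condition labels (with or without a corner
  cell), first column holds gene labels;
* headerless — a bare numeric table; labels ``g1..gn`` / ``c1..cm`` are
  generated.

Missing entries (empty tab-delimited fields or marker tokens such as
``NA``) are recorded in a boolean mask and stored as NaN until
:func:`impute_missing` replaces them by uniform random draws, the way
classic δ-biclustering pipelines preprocess the yeast cell-cycle and
human B-cell compendia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MatrixParseError, ParameterError

#: tokens treated as a missing value in addition to the empty field
DEFAULT_MISSING_MARKERS = frozenset({"", "NA", "na", "nan", "NaN", "NAN", "?"})


@dataclass
class ExpressionMatrix:
    """An n×m expression matrix with labels and a missing-value mask.

    Attributes
    ----------
    values :
        Float array of shape (n, m); originally-missing cells hold NaN
        until imputed.
    gene_ids, condition_ids :
        Unique row / column labels.
    missing_mask :
        Boolean array of shape (n, m); True where the source file had a
        missing entry (the mask is kept after imputation so provenance
        is not lost).
    """

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("expression values must be a 2-D array")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ParameterError(f"matrix must be at least 2x2, got {n}x{m}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ParameterError("missing_mask shape does not match values")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        if len(self.gene_ids) != n:
            raise ParameterError("gene_ids length does not match row count")
        if len(self.condition_ids) != m:
            raise ParameterError("condition_ids length does not match column count")
        if len(set(self.gene_ids)) != n:
            raise ParameterError("gene_ids are not unique")
        if len(set(self.condition_ids)) != m:
            raise ParameterError("condition_ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.gene_ids),
            list(self.condition_ids),
            self.missing_mask.copy(),
        )


def _tokenize(line: str) -> list[str]:
    # tab-delimited files keep empty fields (missing cells); bare
    # whitespace tables cannot represent them, so markers must be used
    if "\t" in line:
        return [tok.strip() for tok in line.rstrip("\n").split("\t")]
    return line.split()


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return not math.isnan(float(tok))


def read_matrix(path: str | Path, missing_marker: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from a delimited text file.

    Parameters
    ----------
    path :
        File to read.
    missing_marker :
        Extra token to treat as missing, on top of the defaults
        (empty field, ``NA``, ``nan`` and case variants, ``?``).
    """
    markers = set(DEFAULT_MISSING_MARKERS)
    if missing_marker is not None:
        markers.add(missing_marker)

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise MatrixParseError(f"{path}: need at least 2 rows, found {len(lines)}")
    rows = [_tokenize(ln) for ln in lines]

    def cell(tok: str, lineno: int) -> float:
        if tok in markers:
            return np.nan
        if _is_number(tok):
            return float(tok)
        raise MatrixParseError(f"{path}: line {lineno}: non-numeric cell {tok!r}")

    first = rows[0]
    headerless = all(tok in markers or _is_number(tok) for tok in first)

    if headerless:
        width = len(first)
        data = []
        for i, row in enumerate(rows):
            if len(row) != width:
                raise MatrixParseError(
                    f"{path}: line {i + 1}: expected {width} fields, found {len(row)}"
                )
            data.append([cell(tok, i + 1) for tok in row])
        values = np.array(data, dtype=float)
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
        condition_ids = [f"c{j + 1}" for j in range(values.shape[1])]
    else:
        body_width = len(rows[1])
        # header may or may not carry a corner cell above the gene labels
        if len(first) == body_width:
            condition_ids = first[1:]
        elif len(first) == body_width - 1:
            condition_ids = first
        else:
            raise MatrixParseError(
                f"{path}: line 1: header has {len(first)} fields, "
                f"body rows have {body_width}"
            )
        data = []
        gene_ids = []
        for i, row in enumerate(rows[1:], start=2):
            if len(row) != body_width:
                raise MatrixParseError(
                    f"{path}: line {i}: expected {body_width} fields, found {len(row)}"
                )
            gene_ids.append(row[0])
            data.append([cell(tok, i) for tok in row[1:]])
        values = np.array(data, dtype=float)

    mask = np.isnan(values)
    return ExpressionMatrix(values, gene_ids, condition_ids, mask)


def write_matrix(M: ExpressionMatrix, path: str | Path, missing_repr: str = "NA") -> None:
    """Write a matrix in the labeled tab-delimited dialect."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(M.condition_ids) + "\n")
        for gid, row, miss in zip(M.gene_ids, M.values, M.missing_mask):
            cells = [
                missing_repr if (mm and np.isnan(v)) else repr(float(v))
                for v, mm in zip(row, miss)
            ]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def impute_missing(
    M: ExpressionMatrix,
    low: float,
    high: float,
    seed: int | np.random.Generator = 0,
) -> ExpressionMatrix:
    """Replace masked cells by independent uniform draws on [low, high].

    Unmasked cells are returned bit-identical; the missing mask is kept
    so downstream code can still tell which cells were imputed.  The
    same seed always yields the same imputed matrix.
    """
    if not low < high:
        raise ParameterError(f"imputation bounds must satisfy low < high, got [{low}, {high}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = M.copy()
    k = int(M.missing_mask.sum())
    if k:
        out.values[M.missing_mask] = rng.uniform(low, high, size=k)
    return out
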