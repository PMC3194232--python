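"""Sigma-method leader selection.

Each objective vector (normalized to non-negative coordinates) is
assigned a direction-like sigma value; for three objectives this is the
cyclic pairwise-difference vector

    σ(f) = (f1² − f2², f2² − f3², f3² − f1²) / (f1² + f2² + f3²),

which is scale-invariant (all vectors on a ray from the origin share a
σ).  A population member's best local guide is the archive member whose
σ lies at minimum Euclidean distance from its own — the archive solution
pulling in the most similar trade-off direction.
"""

from __future__ import annotations

import numpy as np

from .bicluster import ObjectiveVector
from .errors import GuideError
from .pareto import Archive, ArchiveMember


def sigma(f: np.ndarray) -> np.ndarray:
    """Sigma value of one non-negative 3-vector (zero vector → zero σ)."""
    return sigma_many(np.asarray(f, dtype=float)[None, :])[0]


def sigma_many(F: np.ndarray) -> np.ndarray:
    """Row-wise sigma values of an (k, 3) array of non-negative vectors."""
    sq = np.asarray(F, dtype=float) ** 2
    denom = sq.sum(axis=1, keepdims=True)
    out = np.stack(
        [sq[:, 0] - sq[:, 1], sq[:, 1] - sq[:, 2], sq[:, 2] - sq[:, 0]], axis=1
    )
    safe = np.where(denom > 0, denom, 1.0)
    return np.where(denom > 0, out / safe, 0.0)


def archive_sigmas(A: Archive) -> np.ndarray:
    if not A.members:
        raise GuideError("cannot compute guides against an empty archive")
    return sigma_many(np.stack([A.normalize(m.objectives.values) for m in A.members]))


def guide_indices(F: np.ndarray, A: Archive) -> tuple[np.ndarray, np.ndarray]:
    """Best-local-guide archive index and σ-distance for each row of ``F``.

    ``F`` holds raw objective vectors; they are normalized with the
    archive's bounds before σ computation.  Ties go to the lowest
    archive index, so selection is deterministic given archive order.
    """
    sig_a = archive_sigmas(A)
    sig_p = sigma_many(np.stack([A.normalize(f) for f in np.atleast_2d(F)]))
    d = np.linalg.norm(sig_p[:, None, :] - sig_a[None, :, :], axis=-1)
    idx = d.argmin(axis=1)  # argmin takes the first minimum: stable ties
    return idx, d[np.arange(len(d)), idx]


def best_local_guide(antigen_f: ObjectiveVector, A: Archive) -> ArchiveMember:
    """Archive member minimizing σ-distance to the antigen's σ value."""
    idx, _ = guide_indices(antigen_f.values[None, :], A)
    return A.members[int(idx[0])]
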