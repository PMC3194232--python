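"""Pareto dominance, crowding distance and the ε-dominance box archive.

Dominance is constrained by the δ threshold on MSR: a feasible solution
dominates any infeasible one, while within a feasibility class standard
minimization dominance applies to the (MSR, −volume, −row variance)
triple.  Note that an infeasible solution can never dominate a feasible
one even without the constraint rule, because its MSR is strictly
larger; the constraint only strengthens the feasible side.  Ranking
helpers therefore expose a ``constrained`` switch — the clonal-selection
machinery ranks the evolving population unconstrained so that
still-infeasible lineages descending toward the δ region keep receiving
clones, which an MSR-only or feasible-first order provably starves.

The archive discretizes objective space into boxes of side ε.  Raw
objectives span four to five decades on expression data (MSR of a
random submatrix vs. MSR of a coherent bicluster), so box coordinates
are computed on log-compressed objectives (log1p of each magnitude)
min–max normalized to [0, 1]; the normalization bounds follow the
population with hysteresis (a rebuild only happens when padded bounds
are escaped, since every rebuild can merge boxes and shed members).  At
most one solution is kept per box, no kept box is dominated by another,
and when two solutions collide in a box the one closer (Euclidean) to
the box's lower corner wins, ties resolved for the incumbent — the
usual ε-Pareto-set guarantees: convergence with bounded size and
enforced spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bicluster import Bicluster, ObjectiveVector
from .errors import ParameterError


# ---------------------------------------------------------------------------
# dominance


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff ``a`` constrained-dominates ``b`` (minimization)."""
    if a.feasible and not b.feasible:
        return True
    if b.feasible and not a.feasible:
        return False
    return bool(np.all(a.values <= b.values) and np.any(a.values < b.values))


def dominance_matrix(
    vectors: Sequence[ObjectiveVector], constrained: bool = True
) -> np.ndarray:
    """Boolean matrix D with D[i, j] = "i dominates j" (vectorized)."""
    k = len(vectors)
    if k == 0:
        return np.zeros((0, 0), dtype=bool)
    F = np.stack([v.values for v in vectors])
    le = np.all(F[:, None, :] <= F[None, :, :], axis=-1)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=-1)
    dom = le & lt
    if constrained:
        feas = np.array([v.feasible for v in vectors])
        dom = (dom & (feas[:, None] == feas[None, :])) | (
            feas[:, None] & ~feas[None, :]
        )
    np.fill_diagonal(dom, False)
    return dom


def nondominated_mask(
    vectors: Sequence[ObjectiveVector], constrained: bool = True
) -> np.ndarray:
    """Boolean mask of the non-dominated members."""
    if len(vectors) == 0:
        return np.zeros(0, dtype=bool)
    return ~dominance_matrix(vectors, constrained).any(axis=0)


def pareto_ranks(
    vectors: Sequence[ObjectiveVector], constrained: bool = True
) -> np.ndarray:
    """Front index of each solution (0 = non-dominated), Deb's fast sort."""
    dom = dominance_matrix(vectors, constrained)
    k = len(vectors)
    count = dom.sum(axis=0)
    rank = np.full(k, -1, dtype=int)
    r = 0
    while True:
        front = np.flatnonzero((count == 0) & (rank < 0))
        if front.size == 0:
            break
        rank[front] = r
        count = count - dom[front].sum(axis=0)
        r += 1
    return rank


# ---------------------------------------------------------------------------
# crowding distance


def crowding_distance(front: Sequence[ObjectiveVector] | np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of each member of a front.

    Boundary solutions per objective get +inf; interior ones accumulate
    the normalized gap between their neighbours; a degenerate objective
    (max == min) contributes nothing.
    """
    F = front if isinstance(front, np.ndarray) else np.stack([v.values for v in front])
    k, n_obj = F.shape
    if k == 0:
        raise ParameterError("crowding distance of an empty front")
    dist = np.zeros(k)
    for j in range(n_obj):
        order = np.argsort(F[:, j], kind="stable")
        lo, hi = F[order[0], j], F[order[-1], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi > lo and k > 2:
            gaps = (F[order[2:], j] - F[order[:-2], j]) / (hi - lo)
            dist[order[1:-1]] += gaps
    return dist


# ---------------------------------------------------------------------------
# ε-dominance archive


def box_index(f: np.ndarray, epsilon: np.ndarray) -> tuple[int, ...]:
    """Box coordinates floor(f_i / ε_i) of a non-negative objective vector."""
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any(epsilon <= 0):
        raise ParameterError("all box widths must be positive")
    return tuple(int(v) for v in np.floor(np.asarray(f, dtype=float) / epsilon))


def _box_dominates(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
    return a != b and all(x <= y for x, y in zip(a, b))


def log_compress(values: np.ndarray) -> np.ndarray:
    """Map a raw (MSR, −volume, −row variance) triple onto log scale,
    preserving the minimization order of every component."""
    v = np.asarray(values, dtype=float)
    return np.array(
        [
            np.log1p(max(v[0], 0.0)),
            -np.log1p(max(-v[1], 0.0)),
            -np.log1p(max(-v[2], 0.0)),
        ]
    )


@dataclass
class ArchiveMember:
    bicluster: Bicluster
    objectives: ObjectiveVector
    box: tuple[int, ...]
    tag: int = 0  # generation at which the member entered the archive


@dataclass
class Archive:
    """The ε-Pareto set of solutions found so far.

    ``scale`` selects the coordinate map used before min–max
    normalization: ``"log"`` (default, suits raw expression objectives)
    or ``"linear"`` (identity; convenient when objectives are already
    normalized).  ``capacity`` bounds the member count via
    crowding-distance truncation, dropping infeasible members first.
    """

    epsilon: np.ndarray = field(default_factory=lambda: np.full(3, 0.02))
    capacity: int | None = 200
    scale: str = "log"
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    members: list[ArchiveMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (3,) or np.any(self.epsilon <= 0):
            raise ParameterError("epsilon must be 3 positive reals")
        if self.scale not in ("log", "linear"):
            raise ParameterError(f"unknown archive scale {self.scale!r}")
        if self.lo is not None:
            self.lo = self._compress(np.asarray(self.lo, dtype=float))
        if self.hi is not None:
            self.hi = self._compress(np.asarray(self.hi, dtype=float))

    def __len__(self) -> int:
        return len(self.members)

    # -- coordinates ----------------------------------------------------

    def _compress(self, values: np.ndarray) -> np.ndarray:
        return log_compress(values) if self.scale == "log" else np.asarray(values, float)

    def normalize(self, values: np.ndarray) -> np.ndarray:
        """Map raw objectives into [0, 1] (compressed scale, clipped)."""
        if self.lo is None or self.hi is None:
            raise ParameterError("archive normalization bounds are unset")
        c = self._compress(values)
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.clip((c - self.lo) / span, 0.0, 1.0)

    def _box_of(self, values: np.ndarray) -> tuple[int, ...]:
        return box_index(self.normalize(values), self.epsilon)

    # -- normalization maintenance --------------------------------------

    def refresh_bounds(self, extra: Iterable[np.ndarray] = (), pad: float = 0.05) -> None:
        """Track the objective ranges of archive ∪ ``extra`` raw vectors.

        Bounds are padded and only replaced (with a rebuild) when the
        current padded bounds are escaped — rebuilds merge boxes and can
        shed members, so they are kept rare.
        """
        pts = [self._compress(m.objectives.values) for m in self.members]
        pts += [self._compress(np.asarray(v, dtype=float)) for v in extra]
        if not pts:
            return
        P = np.stack(pts)
        lo, hi = P.min(axis=0), P.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        plo, phi = lo - pad * span, hi + pad * span
        if self.lo is None or np.any(lo < self.lo) or np.any(hi > self.hi):
            self._rebuild(plo, phi)

    def _rebuild(self, lo: np.ndarray, hi: np.ndarray) -> None:
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        old = self.members
        self.members = []
        for mem in old:
            self.update(mem.bicluster, mem.objectives, tag=mem.tag)

    # -- update ----------------------------------------------------------

    def update(self, bicluster: Bicluster, f: ObjectiveVector, tag: int = 0) -> bool:
        """Offer one solution to the archive; True iff it was accepted."""
        c = self._compress(f.values)
        if self.lo is None:
            self.lo, self.hi = c - 0.5, c + 0.5
        elif np.any(c < self.lo) or np.any(c > self.hi):
            span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
            self._rebuild(np.minimum(self.lo, c - 0.05 * span),
                          np.maximum(self.hi, c + 0.05 * span))

        shifted = self.normalize(f.values)
        box = box_index(shifted, self.epsilon)

        same = [i for i, m in enumerate(self.members) if m.box == box]
        if same:
            incumbent = self.members[same[0]]
            corner = np.asarray(box) * self.epsilon
            d_new = float(np.linalg.norm(shifted - corner))
            d_old = float(
                np.linalg.norm(self.normalize(incumbent.objectives.values) - corner)
            )
            if d_new < d_old:
                self.members[same[0]] = ArchiveMember(bicluster, f, box, tag)
                return True
            return False

        if any(_box_dominates(m.box, box) for m in self.members):
            return False
        self.members = [m for m in self.members if not _box_dominates(box, m.box)]
        self.members.append(ArchiveMember(bicluster, f, box, tag))
        self._truncate()
        return True

    def _truncate(self) -> None:
        if self.capacity is None:
            return
        while len(self.members) > self.capacity:
            F = np.stack([self.normalize(m.objectives.values) for m in self.members])
            dist = crowding_distance(F)
            infeasible = [
                i for i, m in enumerate(self.members) if not m.objectives.feasible
            ]
            pool = infeasible if infeasible else range(len(self.members))
            self.members.pop(min(pool, key=lambda i: dist[i]))

    # -- views -----------------------------------------------------------

    def objective_matrix(self) -> np.ndarray:
        return np.stack([m.objectives.values for m in self.members])

    def feasible_members(self) -> list[ArchiveMember]:
        return [m for m in self.members if m.objectives.feasible]


# ---------------------------------------------------------------------------
# hypervolume (3-D, minimization)


def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    pts = points[np.all(points < ref, axis=1)]
    if len(pts) == 0:
        return 0.0
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    area = 0.0
    best_y = ref[1]
    for x, y in pts:
        if y < best_y:
            area += (ref[0] - x) * (best_y - y)
            best_y = y
    return float(area)


def hypervolume(points: Iterable[np.ndarray] | np.ndarray, ref=(1.0, 1.0, 1.0)) -> float:
    """Dominated hypervolume of 3-D minimization points w.r.t. ``ref``.

    Slab sweep over the third objective with a 2-D staircase per slab;
    points that do not dominate the reference are dropped.
    """
    ref = np.asarray(ref, dtype=float)
    P = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if P.size == 0:
        return 0.0
    P = P[np.all(P < ref, axis=1)]
    if len(P) == 0:
        return 0.0
    P = P[np.argsort(P[:, 2], kind="stable")]
    zs = P[:, 2]
    hv = 0.0
    for k in range(len(P)):
        z_top = zs[k + 1] if k + 1 < len(P) else ref[2]
        if z_top > zs[k]:
            hv += _hv2d(P[: k + 1, :2], ref[:2]) * (z_top - zs[k])
    return float(hv)
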