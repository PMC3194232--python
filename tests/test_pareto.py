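import numpy as np
import pytest

import dmoiob as dm
from dmoiob.bicluster import ObjectiveVector
from dmoiob.errors import ParameterError
from dmoiob.pareto import box_index, log_compress

B = dm.Bicluster(np.ones(2, bool), np.ones(2, bool))


def vec(a, b, c, feasible=True):
    return ObjectiveVector(np.array([a, b, c], dtype=float), feasible)


def linear_archive(eps=1.0, capacity=None):
    return dm.Archive(
        epsilon=np.full(3, eps), capacity=capacity, scale="linear",
        lo=np.zeros(3), hi=np.ones(3),
    )


class TestDominates:
    def test_componentwise(self):
        assert dm.dominates(vec(1, 1, 1), vec(2, 2, 2))
        assert not dm.dominates(vec(2, 2, 2), vec(1, 1, 1))

    def test_incomparable(self):
        assert not dm.dominates(vec(1, 2, 0), vec(2, 1, 0))
        assert not dm.dominates(vec(2, 1, 0), vec(1, 2, 0))

    def test_equal_vectors_do_not_dominate(self):
        assert not dm.dominates(vec(1, 2, 3), vec(1, 2, 3))

    def test_feasible_dominates_infeasible(self):
        assert dm.dominates(vec(5, 5, 5, True), vec(1, 1, 1, False))
        assert not dm.dominates(vec(1, 1, 1, False), vec(5, 5, 5, True))

    def test_nondominated_mask_matches_pairwise(self, rng):
        vs = [vec(*rng.random(3)) for _ in range(40)]
        mask = dm.nondominated_mask(vs)
        for i, v in enumerate(vs):
            expect = not any(dm.dominates(u, v) for u in vs)
            assert mask[i] == expect


class TestBoxIndex:
    def test_origin(self):
        assert box_index(np.zeros(3), np.array([0.3, 0.1, 0.7])) == (0, 0, 0)

    def test_floor_division(self):
        assert box_index(np.array([0.25, 0.33, 0.10]), np.full(3, 0.1)) == (2, 3, 1)

    def test_boundary_belongs_to_upper_box(self):
        assert box_index(np.array([0.2, 0.2, 0.2]), np.full(3, 0.1)) == (2, 2, 2)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ParameterError):
            box_index(np.zeros(3), np.array([0.1, 0.0, 0.1]))


class TestCrowdingDistance:
    def test_single_member_is_infinite(self):
        assert dm.crowding_distance([vec(1, 2, 3)])[0] == np.inf

    def test_normalized_gap_sum(self):
        front = [vec(0, 1, 0), vec(0.5, 0.5, 0), vec(1, 0, 0)]
        d = dm.crowding_distance(front)
        assert d[0] == np.inf and d[2] == np.inf
        assert d[1] == pytest.approx(2.0)

    def test_duplicated_extremes_stay_infinite(self):
        front = [vec(0, 1, 0), vec(0, 1, 0), vec(1, 0, 0)]
        d = dm.crowding_distance(front)
        assert np.isinf(d).sum() >= 2


class TestArchiveUpdate:
    def test_empty_archive_accepts_anything(self):
        A = linear_archive()
        assert A.update(B, vec(0.5, 0.5, 0.5))
        assert len(A) == 1

    def test_same_box_keeps_corner_closest(self):
        A = linear_archive(eps=1.0)
        A.update(B, vec(0.2, 0.2, 0.2))   # corner distance 0.346
        assert not A.update(B, vec(0.3, 0.4, 0.3))  # distance 0.583
        assert len(A) == 1
        assert A.members[0].objectives.values[1] == pytest.approx(0.2)

    def test_box_dominance_rejects(self):
        A = linear_archive(eps=0.5)
        A.update(B, vec(0.1, 0.1, 0.1))        # box (0,0,0)
        assert not A.update(B, vec(0.6, 0.1, 0.1))  # box (1,0,0)
        assert len(A) == 1

    def test_dominating_box_evicts(self):
        A = linear_archive(eps=0.5)
        A.update(B, vec(0.6, 0.1, 0.1))
        assert A.update(B, vec(0.1, 0.1, 0.1))
        assert len(A) == 1
        assert A.members[0].objectives.values[0] == pytest.approx(0.1)

    def test_update_is_idempotent(self):
        A = linear_archive(eps=0.25)
        f = vec(0.3, 0.6, 0.1)
        A.update(B, f)
        snapshot = [(m.box, tuple(m.objectives.values)) for m in A.members]
        assert not A.update(B, f)
        assert [(m.box, tuple(m.objectives.values)) for m in A.members] == snapshot

    def test_members_mutually_box_nondominated_after_random_stream(self, rng):
        A = linear_archive(eps=0.1)
        for _ in range(2000):
            A.update(B, vec(*rng.random(3)))
        boxes = [m.box for m in A.members]
        assert len(set(boxes)) == len(boxes)
        for i, a in enumerate(boxes):
            for j, b in enumerate(boxes):
                if i != j:
                    assert not (all(x <= y for x, y in zip(a, b)) and a != b)

    def test_capacity_truncation_bounds_size(self, rng):
        A = linear_archive(eps=0.01, capacity=30)
        for _ in range(800):
            A.update(B, vec(*rng.random(3)))
        assert len(A) <= 30


class TestLogCompression:
    def test_order_preserving_per_component(self, rng):
        for _ in range(50):
            a, b = rng.uniform(-5000, 5000, 3), rng.uniform(-5000, 5000, 3)
            a[0], b[0] = abs(a[0]), abs(b[0])
            a[1:], b[1:] = -abs(a[1:]), -abs(b[1:])
            ca, cb = log_compress(a), log_compress(b)
            for i in range(3):
                if a[i] < b[i]:
                    assert ca[i] < cb[i]


class TestHypervolume:
    def test_single_point_box(self):
        assert dm.hypervolume(np.array([[0.5, 0.5, 0.5]])) == pytest.approx(0.125)

    def test_dominated_point_adds_nothing(self):
        pts = np.array([[0.2, 0.2, 0.2], [0.5, 0.5, 0.5]])
        only = dm.hypervolume(pts[:1])
        assert dm.hypervolume(pts) == pytest.approx(only)

    def test_against_monte_carlo(self, rng):
        pts = rng.random((12, 3))
        hv = dm.hypervolume(pts)
        samples = rng.random((200_000, 3))
        dominated = np.any(
            np.all(samples[:, None, :] >= pts[None, :, :], axis=-1), axis=1
        )
        assert hv == pytest.approx(float(dominated.mean()), abs=0.01)

    def test_monotone_under_insertion(self, rng):
        pts = list(rng.random((5, 3)))
        base = dm.hypervolume(np.array(pts))
        pts.append(rng.random(3))
        assert dm.hypervolume(np.array(pts)) >= base - 1e-12
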