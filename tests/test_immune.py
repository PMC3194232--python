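import numpy as np
import pytest

import dmoiob as dm
from dmoiob.bicluster import objectives
from dmoiob.errors import ParameterError
from dmoiob.immune import (
    Antibody,
    MutationParams,
    Population,
    clone_pool,
    select_clone_candidates,
    truncate_population,
)


def hamming(a, b):
    return int(
        (a.gene_mask != b.gene_mask).sum() + (a.condition_mask != b.condition_mask).sum()
    )


def make_population(M, delta, rng, size=30, n_min=5, n_max=60):
    n, m = M.shape
    ab = [
        Antibody(b, objectives(M, b, delta))
        for b in (dm.random_bicluster(n, m, rng) for _ in range(size))
    ]
    return Population(ab, n_min=n_min, n_max=n_max)


@pytest.fixture
def setup(small_matrix, rng):
    M = small_matrix
    pop = make_population(M, 300.0, rng)
    A = dm.Archive()
    A.refresh_bounds([a.objectives.values for a in pop.antibodies])
    for a in pop.antibodies:
        A.update(a.bicluster, a.objectives)
    return M, pop, A


class TestMutate:
    def test_near_single_flip(self, rng):
        params = MutationParams(k_near=1, k_far=3)
        b = dm.Bicluster(np.ones(10, bool), np.ones(6, bool))
        child = dm.mutate(b, near=True, rng=rng, params=params)
        assert hamming(b, child) == 1

    def test_far_flip_count_in_range(self, rng):
        params = MutationParams(k_near=2, k_far=6)
        b = dm.Bicluster(np.ones(20, bool), np.ones(10, bool))
        for _ in range(30):
            child = dm.mutate(b, near=False, rng=rng, params=params)
            assert 3 <= hamming(b, child) <= 6

    def test_repair_keeps_min_size(self, rng):
        params = MutationParams(k_near=4, k_far=8, min_genes=2, min_conditions=2)
        b = dm.Bicluster(
            np.array([True, True] + [False] * 8), np.array([True, True] + [False] * 4)
        )
        for _ in range(100):
            child = dm.mutate(b, near=True, rng=rng, params=params)
            assert child.n_genes >= 2 and child.n_conditions >= 2

    def test_fixed_seed_reproducible(self):
        b = dm.Bicluster(np.ones(12, bool), np.ones(8, bool))
        p = MutationParams(k_near=2, k_far=5)
        c1 = dm.mutate(b, True, np.random.default_rng(9), p)
        c2 = dm.mutate(b, True, np.random.default_rng(9), p)
        np.testing.assert_array_equal(c1.gene_mask, c2.gene_mask)
        np.testing.assert_array_equal(c1.condition_mask, c2.condition_mask)


class TestSelectCloneCandidates:
    def test_r1_zero_selects_nothing(self, rng):
        assert select_clone_candidates(list(range(10)), rng, r1=0.0) == []

    def test_r1_one_selects_all(self, rng):
        got = select_clone_candidates(list(range(10)), rng, r1=1.0)
        assert sorted(got) == list(range(10))

    def test_floor_of_fraction(self, rng):
        got = select_clone_candidates(list(range(10)), rng, r1=0.55)
        assert len(got) == 5
        assert len(set(got)) == 5  # without replacement


class TestPopulationAdd:
    def test_empty_candidate_list_leaves_population(self, setup, rng):
        M, pop, A = setup
        out = dm.population_add(pop, A, M, 300.0, rng, r1=0.0)
        assert len(out) == len(pop)

    def test_counting_contract(self, setup, rng):
        M, pop, A = setup
        params = MutationParams(c_min=1, c_max=1, k_near=1, k_far=2)
        out = dm.population_add(pop, A, M, 300.0, rng, params=params, r1=1.0)
        pool_size = len(clone_pool(pop, A))
        # one clone per candidate, candidates = whole pool, before dedup/truncation
        assert len(out) <= min(pop.n_max, len(pop) + pool_size)
        assert len(out) > len(pop)

    def test_cap_respected(self, small_matrix, rng):
        M = small_matrix
        pop = make_population(M, 300.0, rng, size=40, n_max=40)
        A = dm.Archive()
        A.refresh_bounds([a.objectives.values for a in pop.antibodies])
        for a in pop.antibodies:
            A.update(a.bicluster, a.objectives)
        out = dm.population_add(pop, A, M, 300.0, rng, r1=1.0)
        assert len(out) <= 40

    def test_new_antibodies_satisfy_min_size(self, setup, rng):
        M, pop, A = setup
        out = dm.population_add(pop, A, M, 300.0, rng, r1=1.0)
        for a in out.antibodies:
            assert a.bicluster.n_genes >= 2
            assert a.bicluster.n_conditions >= 2


class TestTruncation:
    def test_deduplicates_masks(self, small_matrix, rng):
        M = small_matrix
        b = dm.random_bicluster(8, 5, rng)
        a = Antibody(b, objectives(M, b, 300.0))
        twin = Antibody(b.copy(), objectives(M, b, 300.0))
        kept = truncate_population([a, twin], n_max=10)
        assert len(kept) == 1

    def test_feasible_members_survive_junk_flood(self, small_matrix, rng):
        M = small_matrix
        good_b = dm.Bicluster(
            np.array([True] * 4 + [False] * 4), np.array([True] * 3 + [False] * 2)
        )  # the additive corner: MSR 0
        good = Antibody(good_b, objectives(M, good_b, 300.0))
        junk = [
            Antibody(b, objectives(M, b, 1e-9))
            for b in (dm.random_bicluster(8, 5, rng) for _ in range(80))
        ]
        kept = truncate_population([good] + junk, n_max=20)
        assert any(a.bicluster.key() == good_b.key() for a in kept)
        assert len(kept) <= 20


class TestPopulationDecrease:
    def test_s_zero_is_identity(self, setup, rng):
        M, pop, A = setup
        out = dm.population_decrease(pop, A, 0.0, rng)
        assert out.antibodies == pop.antibodies

    def test_removes_rounded_fraction(self, small_matrix, rng):
        M = small_matrix
        pop = make_population(M, 300.0, rng, size=100, n_min=5, n_max=200)
        A = dm.Archive()
        A.refresh_bounds([a.objectives.values for a in pop.antibodies])
        for a in pop.antibodies:
            A.update(a.bicluster, a.objectives)
        out = dm.population_decrease(pop, A, 0.02, rng)
        assert len(out) == 98

    def test_never_drops_below_n_min(self, small_matrix, rng):
        M = small_matrix
        pop = make_population(M, 300.0, rng, size=10, n_min=10, n_max=50)
        A = dm.Archive()
        A.refresh_bounds([a.objectives.values for a in pop.antibodies])
        for a in pop.antibodies:
            A.update(a.bicluster, a.objectives)
        out = dm.population_decrease(pop, A, 0.2, rng)
        assert len(out) == 10

    def test_invalid_ratio_raises(self, setup, rng):
        M, pop, A = setup
        with pytest.raises(ParameterError):
            dm.population_decrease(pop, A, 1.5, rng)


class TestDynamicBounds:
    def test_bounds_hold_over_many_generations(self, small_matrix, rng):
        M = small_matrix
        pop = make_population(M, 300.0, rng, size=12, n_min=6, n_max=40)
        A = dm.Archive()
        A.refresh_bounds([a.objectives.values for a in pop.antibodies])
        for a in pop.antibodies:
            A.update(a.bicluster, a.objectives)
        params = MutationParams(k_near=1, k_far=3)
        for t in range(100):
            A.refresh_bounds(a.objectives.values for a in pop.antibodies)
            pop = dm.population_add(pop, A, M, 300.0, rng, params=params, tag=t)
            pop = dm.population_decrease(pop, A, 0.02, rng)
            assert 6 <= len(pop) <= 40
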