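import itertools

import numpy as np
import pytest

from mutualnet.metrics import (
    barber_q,
    connectance,
    dprime,
    h2prime,
    modularity,
    species_degree,
    species_metrics,
    species_strength,
    wnodf,
)

from conftest import mk
from oracles import (
    barber_q_brute,
    dmin_exhaustive,
    entropy_extremes_exhaustive,
    wnodf_brute,
)


class TestConnectance:
    def test_study_richness_arithmetic(self):
        # 110 links in an 18-bird x 14-plant web
        w = np.zeros((14, 18), dtype=np.int64)
        cells = [(i, j) for i in range(14) for j in range(18)]
        for i, j in cells[:110]:
            w[i, j] = 1
        assert connectance(mk(w)) == pytest.approx(110 / 252)

    def test_full_and_single_link(self):
        assert connectance(mk(np.ones((3, 4), dtype=int))) == 1.0
        w = np.zeros((3, 3), dtype=int)
        w[1, 2] = 7
        assert connectance(mk(w)) == pytest.approx(1 / 9)


class TestWnodf:
    def test_perfectly_nested(self):
        assert wnodf(mk([[3, 2, 1], [2, 1, 0]])) == pytest.approx(100.0)

    def test_equal_marginals_contribute_zero(self, identity2):
        assert wnodf(identity2) == 0.0

    def test_matches_brute_force_on_random_matrices(self, random_matrices):
        for matrix in random_matrices:
            assert wnodf(matrix) == pytest.approx(wnodf_brute(matrix.w))

    def test_invariant_under_joint_permutation(self, random_matrices):
        rng = np.random.default_rng(7)
        for matrix in random_matrices[:5]:
            pr = rng.permutation(matrix.n_plants)
            pc = rng.permutation(matrix.n_birds)
            permuted = mk(matrix.w[np.ix_(pr, pc)])
            assert wnodf(permuted) == pytest.approx(wnodf(matrix))

    def test_scale_invariance(self, random_matrices):
        for matrix in random_matrices[:5]:
            assert wnodf(mk(matrix.w * 3)) == pytest.approx(wnodf(matrix))


class TestH2prime:
    def test_diagonal_is_maximally_specialized(self):
        res = h2prime(mk([[5, 0], [0, 5]]))
        assert res.H2 == pytest.approx(np.log(2))
        assert res.H2prime == 1.0

    def test_even_fill_extreme_scores_zero(self):
        # marginals (5,5)/(5,5): the most-even integer fill
        res = h2prime(mk([[3, 2], [2, 3]]))
        assert res.H2prime == 0.0

    def test_extremes_match_exhaustive_enumeration(self):
        marginals = [
            ((3, 2, 1), (3, 2, 1)),
            ((4, 2), (3, 3)),
            ((5, 2, 1), (4, 3, 1)),
        ]
        for r, c in marginals:
            lo, hi = entropy_extremes_exhaustive(r, c)
            res = h2prime(_any_matrix(r, c))
            span = hi - lo
            assert res.H2max >= hi - 0.02 * span
            assert res.H2min <= lo + 0.02 * span

    def test_ordering_invariant(self):
        res = h2prime(mk([[4, 1, 0], [1, 2, 0], [0, 1, 3]]))
        assert res.H2min <= res.H2 <= res.H2max + 1e-12
        assert 0.0 <= res.H2prime <= 1.0

    def test_scaling_changes_h2prime_little(self, random_matrices):
        for matrix in random_matrices[:6]:
            a = h2prime(matrix).H2prime
            b = h2prime(mk(matrix.w * 4)).H2prime
            assert abs(a - b) <= 0.02


def _any_matrix(row_totals, col_totals):
    """A deterministic valid matrix with the given marginals (greedy NW fill)."""
    r = list(row_totals)
    c = list(col_totals)
    w = np.zeros((len(r), len(c)), dtype=np.int64)
    for i in range(len(r)):
        for j in range(len(c)):
            amount = min(r[i], c[j])
            w[i, j] = amount
            r[i] -= amount
            c[j] -= amount
    return mk(w)


class TestModularity:
    def test_block_diagonal_reaches_half(self, identity2):
        res = modularity(identity2, seed=0)
        assert res.Q == pytest.approx(0.5)
        assert res.partition["P1"] == res.partition["B1"]
        assert res.partition["P1"] != res.partition["P2"]

    def test_uniform_matrix_has_no_structure(self, ones2):
        res = modularity(ones2, seed=0)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.partition.values())) == 1

    def test_optimizer_reaches_brute_force_optimum(self, random_matrices):
        for matrix in random_matrices:
            if matrix.n_plants > 4 or matrix.n_birds > 4:
                continue
            res = modularity(matrix, n_restarts=20, seed=11)
            assert res.Q >= barber_q_brute(matrix.w) - 1e-9

    def test_reported_q_matches_partition_evaluation(self, random_matrices):
        for matrix in random_matrices[:5]:
            res = modularity(matrix, seed=3)
            rl = np.array([res.partition[p] for p in matrix.rows])
            cl = np.array([res.partition[b] for b in matrix.cols])
            assert res.Q == pytest.approx(barber_q(matrix, rl, cl))

    def test_seeded_reproducibility(self, random_matrices):
        matrix = random_matrices[0]
        a = modularity(matrix, seed=42)
        b = modularity(matrix, seed=42)
        assert a.Q == b.Q and a.partition == b.partition


class TestSpeciesDegree:
    def test_diagonal(self):
        p, b = species_degree(mk([[2, 0], [0, 3]]))
        assert p.tolist() == [1, 1] and b.tolist() == [1, 1]


class TestSpeciesStrength:
    def test_star_plant_has_full_strength(self):
        p, b = species_strength(mk([[2, 3, 5]]))
        assert p.iloc[0] == pytest.approx(3.0)

    def test_strength_sums_equal_partner_richness(self, random_matrices):
        for matrix in random_matrices:
            p, b = species_strength(matrix)
            assert p.sum() == pytest.approx(matrix.n_birds, abs=1e-12)
            assert b.sum() == pytest.approx(matrix.n_plants, abs=1e-12)

    def test_matches_cell_by_cell_dependency_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.integers(0, 7, size=(5, 4))
        w[w.sum(axis=1) == 0, 0] = 1
        w[0, w.sum(axis=0) == 0] = 1
        matrix = mk(w)
        p, b = species_strength(matrix)
        for j in range(4):
            expected = sum(
                w[i, j] / w[i].sum() for i in range(5) if w[i].sum() > 0
            )
            assert b.iloc[j] == pytest.approx(expected)


class TestDprime:
    def test_proportional_use_is_zero(self):
        # each bird uses plants exactly proportionally to row totals
        w = np.array([[2, 4, 6], [1, 2, 3]])
        _, birds = dprime(mk(w.T))
        assert np.allclose(birds["d"], 0.0)
        assert np.allclose(birds["dprime"], 0.0)

    def test_exclusive_use_of_rarest_plant_saturates(self):
        # B3 puts all 2 events on the rare plant P3 (total 2 = its own total)
        w = np.array([[10, 5, 0], [8, 3, 0], [0, 0, 2]])
        _, birds = dprime(mk(w))
        assert birds.loc["B3", "dprime"] == pytest.approx(1.0)

    def test_dmin_matches_exhaustive_allocation_search(self):
        w = np.array([[4, 1, 0], [2, 3, 1], [0, 1, 2]])
        matrix = mk(w)
        m = matrix.m
        r = matrix.row_totals()
        _, birds = dprime(matrix)
        for j, bird in enumerate(matrix.cols):
            t = int(matrix.col_totals()[j])
            exact = dmin_exhaustive(t, r, m)
            assert birds.loc[bird, "d_min"] <= exact + 0.02 * max(
                birds.loc[bird, "d_max"] - exact, 1e-9
            )

    def test_zero_interaction_species_reported_missing(self):
        w = np.array([[1, 0], [1, 0]])
        matrix = mk(w).drop_empty_species()
        assert matrix.n_birds == 1  # dropped rather than NaN after cleaning


class TestSpeciesMetricsTable:
    def test_shape_and_roles(self, random_matrices):
        matrix = random_matrices[0]
        table = species_metrics(matrix)
        assert len(table) == matrix.n_plants + matrix.n_birds
        assert set(table["role"]) == {"bird", "plant"}
        assert set(table.columns) == {"role", "degree", "strength", "dprime"}
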