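"""Combinatorial objects, probabilities and information matrices."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import choicedesign as cd
from choicedesign.choice_model import (
    Design,
    Utilities,
    complete_matrix,
    incidence_matrix,
    is_laplacian,
    read_design_csv,
    read_utilities_json,
    reduce_matrix,
    scaling_matrices,
    set_information_matrix,
    write_design_csv,
    write_utilities_json,
)


class TestEnumeration:
    def test_small_complete(self):
        assert cd.enumerate_choice_sets(3, 2) == [(1, 2), (1, 3), (2, 3)]

    def test_lexicographic_position(self):
        sets_ = cd.enumerate_choice_sets(6, 3)
        assert len(sets_) == 20
        assert sets_[15] == (2, 5, 6)  # 16th element

    def test_full_set(self):
        assert cd.enumerate_choice_sets(4, 4) == [(1, 2, 3, 4)]

    @pytest.mark.parametrize("m,k", [(3, 1), (3, 4), (2, 0)])
    def test_rejects_bad_sizes(self, m, k):
        with pytest.raises(ValueError):
            cd.enumerate_choice_sets(m, k)


class TestIncidence:
    @pytest.mark.parametrize("m,k", [(4, 2), (4, 3), (6, 3), (6, 4), (7, 5)])
    def test_row_and_column_sums(self, m, k):
        S = incidence_matrix(m, k)
        assert S.shape == (comb(m, k), comb(m, 2))
        assert np.all(S.sum(axis=1) == comb(k, 2))
        assert np.all(S.sum(axis=0) == comb(m - 2, k - 2))

    def test_pairs_give_identity(self):
        assert np.array_equal(incidence_matrix(5, 2), np.eye(10))


class TestProbabilities:
    def test_symmetry(self):
        p = cd.choice_probabilities({1, 2, 3}, np.ones(5))
        assert np.allclose(p, 1 / 3)

    def test_pair(self):
        assert np.allclose(cd.choice_probabilities({1, 2}, np.array([1.0, 3.0])), [0.25, 0.75])

    def test_scale_invariance(self):
        a = cd.choice_probabilities({1, 2}, np.array([1.0, 3.0]))
        b = cd.choice_probabilities({1, 2}, np.array([2.0, 6.0]))
        assert np.allclose(a, b)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cd.choice_probabilities(set(), np.ones(3))


class TestSetInformation:
    def test_pair_at_equal_utilities(self):
        M = set_information_matrix({1, 2}, np.ones(2))
        assert np.allclose(M, [[0.25, -0.25], [-0.25, 0.25]])

    def test_triple_at_equal_utilities(self):
        M = set_information_matrix({1, 2, 3}, np.ones(3))
        off = M[~np.eye(3, dtype=bool)]
        assert np.allclose(off, -1 / 9)

    def test_row_sums_vanish(self, rng):
        pi = np.exp(rng.normal(size=6))
        M = set_information_matrix({2, 4, 5}, pi, m=6)
        assert np.abs(M.sum(axis=1)).max() < 1e-14
        assert np.all(M[:, [0, 2, 5]][[0, 2, 5]] == 0)  # untouched alternatives


class TestInformationMatrix:
    def test_uniform_pairs_m3(self):
        M = cd.information_matrix(Design.uniform(3, 2), np.ones(3))
        off = M[~np.eye(3, dtype=bool)]
        assert np.allclose(off, -1 / 12)

    def test_vertex_design_equals_set_matrix(self, rng):
        pi = np.exp(rng.normal(size=5))
        xi = Design.vertex(5, 3, (1, 3, 4))
        assert np.allclose(cd.information_matrix(xi, pi), set_information_matrix((1, 3, 4), pi, 5))

    def test_equals_convex_combination(self, rng):
        """The edge-weight route agrees with summing per-set matrices."""
        m, k = 6, 3
        pi = np.exp(rng.normal(size=m))
        w = rng.dirichlet(np.ones(comb(m, k)))
        xi = Design(w, m, k)
        direct = sum(
            wj * set_information_matrix(C, pi, m)
            for wj, C in zip(w, cd.enumerate_choice_sets(m, k))
        )
        assert np.allclose(cd.information_matrix(xi, pi), direct, atol=1e-14)

    @pytest.mark.parametrize("m,k", [(3, 2), (5, 3), (8, 4), (8, 2)])
    def test_laplacian_invariants(self, rng, m, k):
        for _ in range(5):
            pi = np.exp(rng.normal(size=m))
            xi = Design(rng.dirichlet(np.ones(comb(m, k))), m, k)
            assert is_laplacian(cd.information_matrix(xi, pi))

    def test_scale_invariance_is_exact(self, rng):
        pi = np.exp(rng.normal(size=4))
        xi = Design(rng.dirichlet(np.ones(6)), 4, 2)
        M1 = cd.information_matrix(xi, pi)
        M2 = cd.information_matrix(xi, 17.3 * pi)
        assert np.allclose(M1, M2, rtol=1e-12)


class TestReduceComplete:
    def test_round_trip_random(self, rng):
        for _ in range(5):
            q = rng.random(comb(5, 2))
            M = cd.information_matrix(Design(rng.dirichlet(np.ones(10)), 5, 2), np.ones(5))
            assert np.allclose(complete_matrix(reduce_matrix(M)), M, atol=1e-15)

    def test_reduced_uniform_m3(self):
        M = cd.information_matrix(Design.uniform(3, 2), np.ones(3))
        assert np.allclose(reduce_matrix(M), [[1 / 6, -1 / 12], [-1 / 12, 1 / 6]])

    def test_complete_scalar(self):
        assert np.allclose(complete_matrix(np.array([[2.0]])), [[2.0, -2.0], [-2.0, 2.0]])

    def test_drop_other_index(self):
        M = cd.information_matrix(Design.uniform(4, 2), np.exp([0.3, -0.1, 0.4, -0.6]))
        red = reduce_matrix(M, drop=1)
        assert np.allclose(complete_matrix(red, drop=1), M, atol=1e-15)


class TestScalingAndQ:
    def test_scaling_matrices_equal_utilities(self):
        prob = cd.ChoiceProblem(3, 2)
        R, L = scaling_matrices(prob, np.ones(3))
        assert np.allclose(R, 4.0) and np.allclose(L, 1.0)

    def test_scaling_entries(self):
        prob = cd.ChoiceProblem(3, 3)
        pi = np.array([1.0, 2.0, 3.0])
        R, L = scaling_matrices(prob, pi)
        assert np.isclose(L[2], 6.0)  # pair {2,3}
        assert np.isclose(R[0], 36.0)  # set {1,2,3}

    def test_uniform_q_m3(self):
        q = cd.q_vector(Design.uniform(3, 2), np.ones(3))
        assert np.allclose(q, 1 / 12)

    def test_matrix_form_equals_elementwise(self, rng):
        """Q = L S^T R^{-1} xi matches the brute-force per-pair sum."""
        m, k = 6, 3
        pi = np.exp(rng.normal(size=m))
        xi = Design(rng.dirichlet(np.ones(comb(m, k))), m, k)
        q = cd.q_vector(xi, pi)
        for idx, (u, v) in enumerate(itertools.combinations(range(1, m + 1), 2)):
            expected = 0.0
            for wj, C in zip(xi.weights, cd.enumerate_choice_sets(m, k)):
                if u in C and v in C:
                    P = pi[np.asarray(C) - 1].sum()
                    expected += pi[u - 1] * pi[v - 1] * wj / P**2
            assert np.isclose(q[idx], expected, rtol=1e-12)

    def test_unsupported_pair_is_zero(self):
        w = np.array([0.5, 0.5, 0.0])
        q = cd.q_vector(Design(w, 3, 2), np.ones(3))
        assert q[2] == 0.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    beta=st.lists(st.floats(-2, 2), min_size=4, max_size=4),
    seed=st.integers(0, 1000),
)
def test_information_matrix_always_laplacian(beta, seed):
    """Any design and positive utilities give a PSD zero-row-sum Z-matrix."""
    rng = np.random.default_rng(seed)
    xi = Design(rng.dirichlet(np.ones(6)), 4, 2)
    assert is_laplacian(cd.information_matrix(xi, np.exp(beta)))


class TestValidationAndIO:
    def test_nonpositive_pi_rejected(self):
        with pytest.raises(ValueError):
            Utilities(np.array([1.0, 0.0, 2.0]))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            Design(np.array([1.2, -0.2, 0.0]), 3, 2)

    def test_sum_not_one_rejected(self):
        with pytest.raises(ValueError):
            Design(np.array([0.5, 0.2, 0.2]), 3, 2)

    def test_design_csv_round_trip(self, tmp_path):
        xi = Design(np.array([0.5, 0.25, 0.25]), 3, 2)
        path = tmp_path / "xi.csv"
        write_design_csv(xi, path)
        back = read_design_csv(path, 3, 2)
        assert np.allclose(back.weights, xi.weights)

    def test_design_csv_duplicate_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("choice_set,weight\n\"1,2\",0.5\n\"2,1\",0.5\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_design_csv(path, 3, 2)

    def test_utilities_json_round_trip(self, tmp_path):
        path = tmp_path / "pi.json"
        write_utilities_json(Utilities(np.array([0.2, 0.3, 0.5])), path, labels=["a", "b", "c"])
        util, labels = read_utilities_json(path)
        assert np.allclose(util.pi, [0.2, 0.3, 0.5])
        assert labels == ["a", "b", "c"]
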