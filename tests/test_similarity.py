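import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from llgcrep.core import (
    DimensionError,
    GraphLevel,
    SimilarityMatrix,
    ValidationError,
    build_integrated_graph,
)
from llgcrep.similarity import (
    SimilarityFusionConfig,
    combine_geometric,
    combine_linear,
    integrated_similarities,
    normalize_sharing_degree,
    pearson,
    sharing_degree_matrix,
    shortest_path_profile_similarity,
)

from conftest import random_network, random_similarity


def _sim(ids, values):
    return SimilarityMatrix(list(ids), np.asarray(values, dtype=float))


class TestSharingDegree:
    @pytest.mark.parametrize(
        "A, expected",
        [
            ([[1, 1, 0], [1, 0, 1]], [[2, 1], [1, 2]]),
            ([[0, 0], [0, 0]], [[0, 0], [0, 0]]),
            ([[1, 1], [1, 1]], [[2, 2], [2, 2]]),  # identical rows: off-diag == diag
        ],
    )
    def test_row_sharing_counts(self, A, expected):
        np.testing.assert_array_equal(
            sharing_degree_matrix(np.array(A), "rows"), np.array(expected)
        )

    def test_column_axis_counts_shared_rows(self):
        A = np.array([[1, 1], [1, 0]])
        np.testing.assert_array_equal(
            sharing_degree_matrix(A, "columns"), np.array([[2, 1], [1, 1]])
        )

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            sharing_degree_matrix(np.array([[2, 0]]), "rows")

    @given(
        arrays(np.int8, (5, 4), elements=st.integers(0, 1)),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_shared_neighbor_count(self, A):
        SD = sharing_degree_matrix(A, "rows")
        for i in range(A.shape[0]):
            for j in range(A.shape[0]):
                manual = sum(int(A[i, c] == 1 and A[j, c] == 1) for c in range(A.shape[1]))
                assert SD[i, j] == manual


class TestNormalizeSharingDegree:
    def test_cosine_normalization(self):
        out = normalize_sharing_degree(np.array([[2, 1], [1, 2]]))
        assert out[0, 1] == pytest.approx(0.5)
        assert out[0, 0] == 1.0

    def test_diagonal_only_matrix_becomes_identity(self):
        np.testing.assert_array_equal(
            normalize_sharing_degree(np.diag([3, 5, 1])), np.eye(3)
        )

    def test_zero_degree_row_gets_zero_similarity_unit_diagonal(self):
        out = normalize_sharing_degree(np.array([[0, 0], [0, 4]]))
        assert out[0, 1] == 0.0
        assert out[0, 0] == 1.0


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3), (1, 3, 2), 0.5),
            ((1, 1, 1), (1, 2, 3), 0.0),  # constant convention
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            pearson([1, 2], [1, 2, 3])


class TestPathProfileSimilarity:
    def _m4(self, net, drug_sim=None, tau=0.5):
        if drug_sim is None:
            drug_sim = _sim(net.drug_ids, np.eye(net.n_drugs))
            tau = 1.0
        return build_integrated_graph(net, GraphLevel.M4, drug_sim, tau=tau)

    def test_identical_neighborhoods_give_similarity_one(self):
        # two drugs associated with the same two diseases (of three)
        from llgcrep.core import TripartiteNetwork

        net = TripartiteNetwork(
            ["d0", "d1"],
            ["s0", "s1", "s2"],
            [],
            np.array([[1, 1, 0], [1, 1, 0]]),
            np.zeros((2, 0)),
            np.zeros((0, 0)),
        )
        sim = shortest_path_profile_similarity(self._m4(net), "drugs")
        assert sim.value("d0", "d1") == pytest.approx(1.0)

    def test_isolated_drug_has_zero_similarity_to_all(self):
        from llgcrep.core import TripartiteNetwork

        net = TripartiteNetwork(
            ["d0", "d1", "d2"],
            ["s0", "s1"],
            [],
            np.array([[1, 0], [0, 1], [0, 0]]),  # d2 isolated: constant profile
            np.zeros((3, 0)),
            np.zeros((0, 0)),
        )
        sim = shortest_path_profile_similarity(self._m4(net), "drugs")
        assert sim.value("d2", "d0") == 0.0
        assert sim.value("d2", "d2") == 1.0

    def test_single_disease_profiles_are_constant_hence_zero(self):
        # profiles of length 1 are constants: convention gives 0 off-diagonal
        from llgcrep.core import TripartiteNetwork

        net = TripartiteNetwork(
            ["d0", "d1"],
            ["s0"],
            [],
            np.array([[1], [1]]),
            np.zeros((2, 0)),
            np.zeros((0, 0)),
        )
        sim = shortest_path_profile_similarity(self._m4(net), "drugs")
        assert sim.value("d0", "d1") == 0.0

    def test_result_is_valid_similarity_matrix(self, tiny_net, tiny_sims):
        drug_sim, _ = tiny_sims
        for kind in ("drugs", "diseases"):
            sim = shortest_path_profile_similarity(self._m4(tiny_net, drug_sim), kind)
            np.testing.assert_allclose(sim.values, sim.values.T)
            assert sim.values.min() >= 0 and sim.values.max() <= 1
            np.testing.assert_allclose(np.diagonal(sim.values), 1.0)


class TestCombination:
    def test_geometric_mean_is_idempotent_for_any_weight(self):
        rng = np.random.default_rng(3)
        S = random_similarity(rng, ["a", "b", "c"])
        for w in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(
                combine_geometric(S, S, w).values, S.values, atol=1e-12
            )

    def test_geometric_weight_one_returns_first_matrix(self):
        S1 = _sim(["a", "b"], [[1, 0.25], [0.25, 1]])
        S2 = _sim(["a", "b"], [[1, 0.9], [0.9, 1]])
        np.testing.assert_allclose(combine_geometric(S1, S2, 1.0).values, S1.values)

    def test_geometric_hand_value(self):
        S1 = _sim(["a", "b"], [[1, 0.25], [0.25, 1]])
        S2 = _sim(["a", "b"], [[1, 1.0], [1.0, 1]])
        assert combine_geometric(S1, S2, 0.5).value("a", "b") == pytest.approx(0.5)

    @pytest.mark.parametrize("lam, expected", [(1.0, 0.2), (0.0, 0.6), (0.5, 0.4)])
    def test_linear_blend(self, lam, expected):
        S_bio = _sim(["a", "b"], [[1, 0.2], [0.2, 1]])
        S_topo = _sim(["a", "b"], [[1, 0.6], [0.6, 1]])
        assert combine_linear(S_bio, S_topo, lam).value("a", "b") == pytest.approx(expected)

    def test_id_mismatch_rejected(self):
        S1 = _sim(["a", "b"], [[1, 0.2], [0.2, 1]])
        S2 = _sim(["a", "c"], [[1, 0.2], [0.2, 1]])
        with pytest.raises(ValidationError):
            combine_geometric(S1, S2, 0.5)
        with pytest.raises(ValidationError):
            combine_linear(S1, S2, 0.5)


class TestIntegratedSimilarities:
    def test_outputs_satisfy_similarity_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = random_network(rng)
            db = random_similarity(rng, net.drug_ids)
            sb = random_similarity(rng, net.disease_ids)
            for sim in integrated_similarities(net, db, sb, SimilarityFusionConfig()):
                v = sim.values
                np.testing.assert_allclose(v, v.T, atol=1e-12)
                assert v.min() >= 0 and v.max() <= 1
                np.testing.assert_allclose(np.diagonal(v), 1.0)

    def test_fusion_weight_bounds_enforced(self):
        with pytest.raises(ValidationError):
            SimilarityFusionConfig(w_sd=1.5)
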