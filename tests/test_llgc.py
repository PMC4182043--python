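import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from llgcrep.core import ValidationError
from llgcrep.llgc import (
    LLGCConfig,
    assign_labels,
    energy,
    initial_labels,
    llgc_closed_form,
    llgc_iterate,
    normalize_operator,
    suggest_sigma0,
    transform_distance,
    weight_matrix,
)


def random_weight_matrix(rng, n):
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestTransformDistance:
    def test_sigma0_is_a_fixed_point(self):
        assert transform_distance(0.12, sigma0=0.12, gamma=2.0) == pytest.approx(0.12)

    def test_zero_maps_to_zero(self):
        assert transform_distance(0.0, sigma0=0.5, gamma=3.0) == 0.0

    def test_hand_value(self):
        assert transform_distance(0.06, sigma0=0.12, gamma=2.0) == pytest.approx(0.03)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            transform_distance(-0.1, sigma0=0.5)

    @given(
        st.floats(1e-6, 10.0),
        st.floats(1e-3, 5.0),
        st.floats(1.0 + 1e-9, 6.0),
    )
    @settings(max_examples=1000, deadline=None)
    def test_order_properties_hold(self, d, sigma0, gamma):
        """Below sigma0 the transform shrinks, above it stretches (gamma > 1)."""
        t = transform_distance(d, sigma0, gamma)
        if d < sigma0:
            assert t <= d + 1e-12
        elif d > sigma0:
            assert t >= d - 1e-12
        assert transform_distance(sigma0, sigma0, gamma) == pytest.approx(sigma0, rel=1e-9)


class TestWeightMatrix:
    def test_identical_rows_give_offdiagonal_one_and_zero_diagonal(self):
        X = np.array([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1]])
        W = weight_matrix(X, LLGCConfig(sigma0=1.0))
        assert W[0, 1] == pytest.approx(1.0)
        np.testing.assert_array_equal(np.diagonal(W), 0.0)

    def test_distance_at_sigma_gives_exp_minus_half(self):
        X = np.array([[0.0], [0.12]])
        W = weight_matrix(X, LLGCConfig(sigma0=0.12, sigma=0.12, gamma=2.0))
        assert W[0, 1] == pytest.approx(np.exp(-0.5))

    def test_properties_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            X = rng.random((12, 5))
            W = weight_matrix(X, LLGCConfig(sigma0=0.5))
            assert np.allclose(W, W.T)
            assert np.diagonal(W).sum() == 0.0
            assert W.min() >= 0 and W.max() <= 1


class TestNormalizeOperator:
    def test_unit_degree_graph_unchanged(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_operator(W), W)

    def test_triangle_entries_are_half(self):
        W = np.ones((3, 3)) - np.eye(3)
        S = normalize_operator(W)
        assert S[0, 1] == pytest.approx(0.5)

    def test_spectral_radius_at_most_one_on_random_instances(self):
        rng = np.random.default_rng(1)
        for n in (5, 20, 50):
            for _ in range(5):
                S = normalize_operator(random_weight_matrix(rng, n))
                lam = np.max(np.abs(np.linalg.eigvalsh(S)))
                assert lam <= 1.0 + 1e-10

    def test_isolated_node_warns_and_zeroes_row(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.warns(UserWarning, match="isolated"):
            S = normalize_operator(W)
        assert S[2].sum() == 0.0


class TestInitialLabels:
    def test_all_unknown_mode_marks_rest_negative(self):
        pairs = [("a", "x"), ("b", "y"), ("c", "z")]
        state = initial_labels(pairs, [("a", "x")])
        np.testing.assert_array_equal(
            state.Y, [[1, 0], [0, 1], [0, 1]]
        )

    def test_none_mode_leaves_unlabeled_rows_zero(self):
        pairs = [("a", "x"), ("b", "y")]
        state = initial_labels(pairs, [("a", "x")], negatives="none")
        np.testing.assert_array_equal(state.Y, [[1, 0], [0, 0]])

    def test_no_known_associations_is_an_error(self):
        with pytest.raises(ValidationError, match="nothing to spread"):
            initial_labels([("a", "x")], [])

    def test_known_pair_outside_pool_is_an_error(self):
        with pytest.raises(ValidationError):
            initial_labels([("a", "x")], [("b", "y")])


class TestSpreading:
    def test_zero_operator_fixes_f_at_scaled_labels(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        F, _ = llgc_iterate(np.zeros((2, 2)), Y, LLGCConfig(alpha=0.7))
        np.testing.assert_allclose(F, 0.3 * Y, atol=1e-8)
        np.testing.assert_allclose(llgc_closed_form(np.zeros((2, 2)), Y), Y)

    def test_two_node_hand_solution(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        Y = np.array([[1.0, 0.0], [0.0, 0.0]])
        cfg = LLGCConfig(alpha=0.5, tol=1e-12, max_iter=5000)
        F_closed = llgc_closed_form(S, Y, cfg)
        np.testing.assert_allclose(F_closed[:, 0], [4 / 3, 2 / 3], atol=1e-12)
        F_iter, _ = llgc_iterate(S, Y, cfg)
        np.testing.assert_allclose(F_iter, 0.5 * F_closed, atol=1e-10)

    def test_iterate_agrees_with_scaled_closed_form_on_random_instances(self):
        rng = np.random.default_rng(2)
        cfg = LLGCConfig(alpha=0.9, tol=1e-12, max_iter=20000)
        for n in (5, 30):
            for _ in range(5):
                S = normalize_operator(random_weight_matrix(rng, n))
                Y = np.zeros((n, 2))
                Y[rng.integers(n), 0] = 1
                Y[:, 1] = 1 - Y[:, 0]
                F_iter, _ = llgc_iterate(S, Y, cfg)
                F_closed = llgc_closed_form(S, Y, cfg)
                assert np.abs(F_iter - (1 - cfg.alpha) * F_closed).max() < 10 * cfg.tol

    def test_ranking_invariant_under_label_rescaling(self):
        rng = np.random.default_rng(3)
        S = normalize_operator(random_weight_matrix(rng, 12))
        Y = np.zeros((12, 2))
        Y[:3, 0] = 1
        Y[3:, 1] = 1
        s1 = llgc_closed_form(S, Y)[:, 0] - llgc_closed_form(S, Y)[:, 1]
        sc = llgc_closed_form(S, 5 * Y)[:, 0] - llgc_closed_form(S, 5 * Y)[:, 1]
        assert np.array_equal(np.argsort(s1), np.argsort(sc))

    def test_nonconvergence_warns(self):
        S = normalize_operator(np.array([[0.0, 1.0], [1.0, 0.0]]))
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="did not converge"):
            llgc_iterate(S, Y, LLGCConfig(alpha=0.99, tol=1e-15, max_iter=3))


class TestEnergy:
    def test_zero_on_edgeless_graph_at_f_equal_y(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert energy(Y, np.zeros((2, 2)), Y) == 0.0

    def test_converged_f_beats_y_and_random_perturbations(self):
        rng = np.random.default_rng(4)
        cfg = LLGCConfig(alpha=0.8)
        W = random_weight_matrix(rng, 15)
        S = normalize_operator(W)
        Y = np.zeros((15, 2))
        Y[:4, 0] = 1
        Y[4:, 1] = 1
        F_star = (1 - cfg.alpha) * llgc_closed_form(S, Y, cfg)
        q_star = energy(F_star, W, Y, cfg)
        assert q_star <= energy(Y, W, Y, cfg)
        for _ in range(100):
            F_pert = F_star + rng.normal(0, 0.01, F_star.shape)
            assert energy(F_pert, W, Y, cfg) > q_star

    def test_energy_decreases_monotonically_along_iteration(self):
        rng = np.random.default_rng(5)
        cfg = LLGCConfig(alpha=0.9)
        W = random_weight_matrix(rng, 10)
        S = normalize_operator(W)
        Y = np.zeros((10, 2))
        Y[0, 0] = 1
        Y[1:, 1] = 1
        F = Y.copy()
        prev = energy(F, W, Y, cfg)
        for _ in range(50):
            F = cfg.alpha * S @ F + (1 - cfg.alpha) * Y
            q = energy(F, W, Y, cfg)
            assert q <= prev + 1e-12
            prev = q


class TestAssignLabels:
    @pytest.mark.parametrize(
        "row, expected",
        [((0.8, 0.1), True), ((0.3, 0.3), False), ((0.1, 0.8), False)],
    )
    def test_rule_and_tie_break(self, row, expected):
        labels, scores = assign_labels(np.array([row]))
        assert labels[0] == expected
        assert scores[0] == pytest.approx(row[0] - row[1])

    def test_known_positive_without_competition_stays_positive(self):
        S = normalize_operator(np.array([[0.0, 1.0], [1.0, 0.0]]))
        Y = np.array([[1.0, 0.0], [1.0, 0.0]])
        F = llgc_closed_form(S, Y, LLGCConfig(alpha=0.5))
        labels, _ = assign_labels(F)
        assert labels.all()

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValidationError):
            assign_labels(np.array([[np.inf, 0.0]]))


class TestSuggestSigma0:
    def test_bimodal_distances_give_sigma0_in_the_gap(self):
        rng = np.random.default_rng(6)
        d = np.concatenate(
            [rng.normal(1.0, 0.05, 2000), rng.normal(3.0, 0.05, 2000)]
        )
        lo, hi, sigma0 = suggest_sigma0(np.abs(d))
        assert 1.0 < lo < sigma0 < hi < 3.0  # band lies between the cluster means
        assert 1.2 < sigma0 < 2.8

    def test_uniform_distances_fall_back_to_median(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0, 1, 5000)
        with pytest.warns(UserWarning, match="median"):
            lo, hi, sigma0 = suggest_sigma0(d)
        assert sigma0 == pytest.approx(np.median(d))
        assert lo == hi == sigma0

    def test_band_midpoint_is_sigma0(self):
        # the published sparse band [0.088, 0.152] has midpoint 0.12
        lo, hi = 0.088, 0.152
        assert (lo + hi) / 2 == pytest.approx(0.12)
        rng = np.random.default_rng(8)
        d = np.abs(
            np.concatenate([rng.normal(0.05, 0.01, 3000), rng.normal(0.20, 0.01, 3000)])
        )
        blo, bhi, sigma0 = suggest_sigma0(d)
        assert sigma0 == pytest.approx((blo + bhi) / 2)

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValidationError):
            suggest_sigma0(np.linspace(0, 1, 50))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.0},
            {"gamma": 0.5},
            {"sigma0": -1.0},
            {"tol": 0.0},
            {"negatives": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            LLGCConfig(**kwargs)
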