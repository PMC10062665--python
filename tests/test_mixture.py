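"""EM fitting of the mixture of Markov chains."""

import itertools
import math

import numpy as np
import pytest

from moodpain.mixture import (
    MixtureModel,
    assign_clusters,
    component_loglik,
    e_step,
    fit_em,
    m_step,
    model_selection_scan,
)
from moodpain.synthetic import (
    CohortSpec,
    attractor_matrix,
    simulate_cohort,
    sticky_matrix,
    transition_count_array,
)


def single_count(i, j, n=2):
    C = np.zeros((1, n, n))
    C[0, i, j] = 1
    return C


class TestComponentLoglik:
    def test_single_transition(self):
        M = np.array([[0.5, 0.5], [0.5, 0.5]])
        ll = component_loglik(single_count(0, 1), M)
        assert ll[0, 0] == pytest.approx(math.log(0.5))

    def test_zero_counts_contribute_nothing_even_on_zero_probability(self):
        M = np.array([[1.0, 0.0], [0.5, 0.5]])
        ll = component_loglik(np.zeros((1, 2, 2)), M)
        assert ll[0, 0] == 0.0

    def test_hand_computed_value(self):
        C = np.array([[[2.0, 0.0], [0.0, 0.0]]])
        M = np.array([[0.9, 0.1], [0.5, 0.5]])
        assert component_loglik(C, M)[0, 0] == pytest.approx(2 * math.log(0.9))

    def test_positive_count_on_zero_probability_is_minus_inf(self):
        M = np.array([[1.0, 0.0], [0.5, 0.5]])
        ll = component_loglik(single_count(0, 1), M)
        assert np.isneginf(ll[0, 0])


class TestEStep:
    def test_closed_form_two_component_ratio(self):
        C = np.zeros((1, 2, 2))
        C[0, 0, 0] = 10
        model = MixtureModel(
            np.array([0.5, 0.5]),
            np.stack([sticky_matrix(0.9, 2), sticky_matrix(0.5, 2)]),
        )
        gamma, _ = e_step(model, C)
        expected = 0.9**10 / (0.9**10 + 0.5**10)
        assert gamma[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_identical_components_give_weights(self):
        M = sticky_matrix(0.7, 3)
        model = MixtureModel(np.array([0.3, 0.7]), np.stack([M, M]))
        C = np.zeros((2, 3, 3))
        C[0, 0, 1] = 4
        gamma, _ = e_step(model, C)
        np.testing.assert_allclose(gamma, [[0.3, 0.7], [0.3, 0.7]])

    def test_zero_count_participant_gets_weights(self):
        model = MixtureModel(
            np.array([0.2, 0.8]),
            np.stack([sticky_matrix(0.9, 2), sticky_matrix(0.5, 2)]),
        )
        gamma, _ = e_step(model, np.zeros((1, 2, 2)))
        np.testing.assert_allclose(gamma[0], [0.2, 0.8])

    def test_impossible_participant_warns_and_goes_uniform(self):
        M = np.array([[1.0, 0.0], [1.0, 0.0]])
        model = MixtureModel(np.array([0.5, 0.5]), np.stack([M, M]))
        with pytest.warns(RuntimeWarning, match="impossible"):
            gamma, ll = e_step(model, single_count(0, 1))
        np.testing.assert_allclose(gamma[0], [0.5, 0.5])
        assert np.isneginf(ll)


class TestMStep:
    def test_k1_reduces_to_pooled_row_normalisation(self):
        rng = np.random.default_rng(2)
        C = rng.integers(0, 20, size=(5, 3, 3)).astype(float)
        model = m_step(np.ones((5, 1)), C, smoothing=0.0)
        pooled = C.sum(axis=0)
        np.testing.assert_allclose(
            model.matrices[0], pooled / pooled.sum(axis=1, keepdims=True)
        )

    def test_hard_responsibilities_give_per_group_mles(self):
        C = np.zeros((2, 2, 2))
        C[0] = [[3, 1], [0, 0]]
        C[1] = [[0, 0], [2, 2]]
        gamma = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = m_step(gamma, C, smoothing=0.0)
        np.testing.assert_allclose(model.matrices[0, 0], [0.75, 0.25])
        np.testing.assert_allclose(model.matrices[1, 1], [0.5, 0.5])

    def test_split_responsibility_gives_identical_components(self):
        C = np.array([[[4.0, 2.0], [1.0, 3.0]]])
        model = m_step(np.array([[0.5, 0.5]]), C, smoothing=0.0)
        np.testing.assert_allclose(model.matrices[0], model.matrices[1])
        rowsum = C[0].sum(axis=1, keepdims=True)
        np.testing.assert_allclose(model.matrices[0], C[0] / rowsum)

    def test_zero_mass_rows_fall_back_to_uniform(self):
        C = np.array([[[2.0, 1.0], [0.0, 0.0]]])
        model = m_step(np.array([[1.0]]), C, smoothing=1e-6)
        np.testing.assert_allclose(model.matrices[0, 1], [0.5, 0.5])


class TestFitEM:
    def test_loglik_trace_monotone_nondecreasing(self, two_component_spec):
        cohort = simulate_cohort(two_component_spec)
        fit = fit_em(cohort.count_array(), K=2, n_restarts=2, seed=0)
        trace = fit.loglik_trace
        assert np.all(np.diff(trace) >= -1e-10 * np.abs(trace[:-1]))

    def test_k1_recovers_pooled_mle_with_unit_responsibilities(self):
        rng = np.random.default_rng(3)
        C = rng.integers(0, 10, size=(8, 4, 4)).astype(float)
        fit = fit_em(C, K=1, n_restarts=1, seed=0, smoothing=0.0)
        pooled = C.sum(axis=0)
        np.testing.assert_allclose(
            fit.model.matrices[0],
            pooled / pooled.sum(axis=1, keepdims=True),
            atol=1e-12,
        )
        np.testing.assert_allclose(fit.gamma, 1.0)

    def test_reproducible_for_fixed_seed(self, two_component_spec):
        cohort = simulate_cohort(two_component_spec)
        C = cohort.count_array()
        a = fit_em(C, K=2, n_restarts=3, seed=42)
        b = fit_em(C, K=2, n_restarts=3, seed=42)
        np.testing.assert_array_equal(a.model.matrices, b.model.matrices)
        assert a.log_likelihood == b.log_likelihood

    def test_rejects_more_components_than_participants(self):
        with pytest.raises(ValueError):
            fit_em(np.ones((2, 2, 2)), K=3)

    def test_em_beats_brute_force_hard_assignment(self):
        """Exhaustive hard-partition oracle on a tiny cohort.

        The mixture optimum dominates the best hard assignment of
        participants to two chains, since hard assignments are a
        subset of the mixture's feasible responsibilities.
        """
        rng = np.random.default_rng(9)
        C = rng.integers(0, 6, size=(5, 2, 2)).astype(float)

        def hard_loglik(assign):
            # complete-data log-likelihood at the hard-assignment MLE:
            # transition terms plus the log mixing-weight of each label
            assign = np.array(assign)
            total = 0.0
            for k in (0, 1):
                group = C[assign == k]
                if not len(group):
                    continue
                total += len(group) * math.log(len(group) / len(C))
                pooled = group.sum(axis=0)
                rows = pooled.sum(axis=1, keepdims=True)
                with np.errstate(divide="ignore", invalid="ignore"):
                    M = np.where(rows > 0, pooled / np.where(rows == 0, 1, rows), 0.5)
                    logM = np.where(pooled > 0, np.log(M), 0.0)
                total += float((pooled * logM).sum())
            return total

        best_hard = max(
            hard_loglik(a) for a in itertools.product((0, 1), repeat=5)
        )
        fit = fit_em(C, K=2, n_restarts=10, seed=1, smoothing=1e-9)
        assert fit.log_likelihood >= best_hard - 1e-6


class TestAssignClusters:
    def test_argmax_assignment(self):
        gamma = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0]])
        assert assign_clusters(gamma).tolist() == [1, 0]  # tie -> lowest index

    def test_hard_gamma_identity(self):
        gamma = np.eye(3)
        assert assign_clusters(gamma).tolist() == [0, 1, 2]


class TestModelSelection:
    def test_single_k_row_has_no_delta(self):
        rng = np.random.default_rng(4)
        C = rng.integers(0, 5, size=(6, 2, 2)).astype(float)
        table = model_selection_scan(C, [1], n_restarts=1, seed=0)
        assert table.K_values.tolist() == [1]
        assert np.isnan(table.delta_neg_loglik[0])

    def test_negll_nonincreasing_in_k(self):
        spec = CohortSpec(
            S=150,
            weights=np.array([0.5, 0.5]),
            matrices=np.stack([sticky_matrix(0.9), attractor_matrix(0)]),
            mean_length=30.0,
            seed=5,
        )
        cohort = simulate_cohort(spec)
        table = model_selection_scan(
            cohort.count_array(), range(1, 4), n_restarts=4, seed=5
        )
        assert np.all(np.diff(table.neg_loglik) <= 1e-6)

    def test_bic_formula(self):
        rng = np.random.default_rng(6)
        C = rng.integers(0, 5, size=(6, 4, 4)).astype(float)
        table = model_selection_scan(C, [2], n_restarts=2, seed=0)
        T = C.sum()
        p = (2 - 1) + 2 * 4 * 3
        assert table.bic[0] == pytest.approx(
            2 * table.neg_loglik[0] + p * math.log(T)
        )
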