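"""Synthetic cohort generator: determinism, law-of-large-numbers checks,
full-scale refinement, and the parameter-recovery harness."""

import numpy as np
import pytest

from moodpain.state_space import full_to_reduced_index
from moodpain.synthetic import (
    CohortSpec,
    attractor_matrix,
    paper_like_spec,
    recovery_harness,
    simulate_cohort,
    simulate_full_scale_states,
    sticky_matrix,
    transition_count_array,
    uniform_refinement,
)


class TestSimulateCohort:
    def test_invalid_spec_lists_violations(self):
        with pytest.raises(ValueError, match="weights"):
            CohortSpec(S=5, weights=np.array([0.5, 0.4]),
                       matrices=np.stack([sticky_matrix(), sticky_matrix()]))

    def test_absorbing_chain_gives_constant_trajectories(self):
        spec = CohortSpec(
            S=20, weights=np.array([1.0]), matrices=np.eye(4)[None],
            mean_length=10.0, seed=0,
        )
        cohort = simulate_cohort(spec)
        for traj in cohort.trajectories:
            assert len(set(traj.states.tolist())) == 1

    def test_lengths_match_draws_when_nothing_is_missing(self):
        spec = CohortSpec(
            S=50, weights=np.array([1.0]), matrices=sticky_matrix()[None],
            mean_length=20.0, gap_prob=0.0, single_score_missing=0.0, seed=1,
        )
        cohort = simulate_cohort(spec)
        lengths = np.array([len(t) for t in cohort.trajectories])
        assert lengths.min() >= 2
        # days are consecutive 0..m-1 when no day is dropped
        for traj in cohort.trajectories:
            assert np.array_equal(traj.days, np.arange(len(traj)))

    def test_empirical_frequencies_match_chain(self):
        M = attractor_matrix(target=0, pull=0.4, stay=0.35)
        spec = CohortSpec(
            S=500, weights=np.array([1.0]), matrices=M[None],
            mean_length=202.0, seed=2,
        )
        cohort = simulate_cohort(spec)
        pooled = cohort.count_array().sum(axis=0).astype(float)
        assert pooled.sum() > 1e5
        freq = pooled / pooled.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(freq, M, atol=0.01)

    def test_identical_spec_and_seed_identical_cohort(self):
        spec = paper_like_spec(S=100, seed=9)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        assert a.diary.equals(b.diary)
        assert np.array_equal(a.labels, b.labels)
        assert a.covariates.equals(b.covariates)

    def test_pooled_counts_converge_to_weight_averaged_chain(self):
        # With shared stationary behaviour absent, pooled transition
        # frequencies approach the row-occupancy-weighted mixture; for a
        # single shared sticky family this reduces to entrywise closeness.
        mats = np.stack([sticky_matrix(0.8), sticky_matrix(0.6)])
        spec = CohortSpec(
            S=2000, weights=np.array([0.5, 0.5]), matrices=mats,
            mean_length=50.0, seed=3,
        )
        cohort = simulate_cohort(spec)
        pooled = cohort.count_array().sum(axis=0).astype(float)
        freq = pooled / pooled.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(freq, mats.mean(axis=0), atol=0.02)

    def test_covariate_prevalence_tracks_cluster(self):
        spec = CohortSpec(
            S=3000, weights=np.array([0.5, 0.5]),
            matrices=np.stack([sticky_matrix(0.9), sticky_matrix(0.5)]),
            mean_length=10.0,
            covariate_model={"flag": np.array([0.8, 0.1])},
            seed=4,
        )
        cohort = simulate_cohort(spec)
        flags = cohort.covariates["flag"].to_numpy()
        prev0 = flags[cohort.labels == 0].mean()
        prev1 = flags[cohort.labels == 1].mean()
        assert prev0 == pytest.approx(0.8, abs=0.05)
        assert prev1 == pytest.approx(0.1, abs=0.05)


class TestFullScaleRefinement:
    def test_round_trip_through_reduced_recoding(self):
        cohort = simulate_cohort(paper_like_spec(S=50, seed=5))
        refined = simulate_full_scale_states(cohort, seed=5)
        mapping = full_to_reduced_index()
        for red, full in zip(cohort.trajectories, refined.trajectories):
            assert np.array_equal(mapping[full.states], red.states)

    def test_degenerate_refinement_is_invertible(self):
        refinement = np.zeros((4, 25))
        mapping = full_to_reduced_index()
        for r in range(4):
            refinement[r, np.nonzero(mapping == r)[0][0]] = 1.0
        cohort = simulate_cohort(paper_like_spec(S=20, seed=6))
        refined = simulate_full_scale_states(cohort, refinement, seed=6)
        for red, full in zip(cohort.trajectories, refined.trajectories):
            assert np.array_equal(mapping[full.states], red.states)
            assert len(set(full.states[red.states == red.states])) <= 4

    def test_uniform_refinement_spreads_gl_over_four_cells(self):
        # GL covers 2 good-mood levels x 2 low-pain levels = 4 Likert pairs
        ref = uniform_refinement()
        mapping = full_to_reduced_index()
        gl_cells = ref[0][mapping == 0]
        assert gl_cells.size == 4
        np.testing.assert_allclose(gl_cells, 1 / 4)

    def test_mass_outside_group_rejected(self):
        bad = uniform_refinement()
        bad[0] = 0.0
        bad[0, 24] = 1.0  # a BH cell claimed for GL
        cohort = simulate_cohort(paper_like_spec(S=5, seed=7))
        with pytest.raises(ValueError, match="outside"):
            simulate_full_scale_states(cohort, bad)


class TestRecoveryHarness:
    def test_well_separated_components_recovered(self, two_component_spec):
        report = recovery_harness(two_component_spec, n_restarts=3)
        assert report.accuracy >= 0.95
        assert report.ari > 0.8

    def test_identical_components_unidentifiable(self):
        M = sticky_matrix(0.7)
        spec = CohortSpec(
            S=200, weights=np.array([0.5, 0.5]), matrices=np.stack([M, M]),
            mean_length=30.0, seed=12,
        )
        report = recovery_harness(spec, n_restarts=2)
        # chance-level: accuracy near the larger mixing weight
        assert report.accuracy < 0.65

    def test_errors_shrink_with_cohort_size(self):
        errors = []
        for S in (100, 800):
            spec = CohortSpec(
                S=S, weights=np.array([0.5, 0.5]),
                matrices=np.stack([sticky_matrix(0.9), sticky_matrix(0.5)]),
                mean_length=40.0, seed=13,
            )
            errors.append(recovery_harness(spec, n_restarts=3).matrix_error)
        assert errors[1] < errors[0]


def test_paper_like_preset_shape():
    spec = paper_like_spec(S=500, seed=0)
    assert spec.K == 4
    np.testing.assert_allclose(spec.weights.sum(), 1.0)
    cohort = simulate_cohort(spec)
    assert len(cohort.trajectories) == 500
    assert set(cohort.covariates.columns) >= {"fibromyalgia", "back_pain"}
    counts = transition_count_array(cohort.trajectories)
    assert counts.shape == (500, 4, 4)
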