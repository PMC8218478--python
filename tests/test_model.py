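"""Mixture density, likelihood and posterior computations against
closed forms and brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcra import (
    LCRAParameters,
    class_membership_probs,
    class_outcome_profile,
    class_sizes,
    log_likelihood,
    mixture_outcome_probs,
    outcome_probs_given_class,
    posterior_class_probs,
)
from lcra.codebook import EncodedDesign

from conftest import random_params


def brute_force_softmax(logits):
    e = [np.exp(v) for v in logits]
    s = sum(e)
    return np.array([v / s for v in e])


def make_design(rng, params, n=10, with_outcome=True):
    Q = params.gamma.shape[1] - 1 if params.n_classes > 1 else 17
    P = params.n_predictors
    return EncodedDesign(
        covariate_matrix=rng.normal(size=(n, Q)),
        predictor_matrix=rng.normal(size=(n, P)),
        outcome_vector=rng.integers(0, 3, size=n) if with_outcome else -np.ones(n, int),
        covariate_names=[f"c{j}" for j in range(Q)],
        predictor_names=[f"p{j}" for j in range(P)],
        reference_levels={},
    )


class TestMembership:
    def test_single_class_is_certain(self):
        params = LCRAParameters(gamma=np.zeros((0, 18)), beta=np.zeros((1, 2, 9)))
        assert class_membership_probs(np.zeros(17), params) == pytest.approx([1.0])

    def test_zero_coefficients_give_uniform(self):
        params = LCRAParameters(gamma=np.zeros((2, 18)), beta=np.zeros((3, 2, 9)))
        probs = class_membership_probs(np.random.default_rng(0).normal(size=17), params)
        np.testing.assert_allclose(probs, [1 / 3] * 3, atol=1e-12)

    def test_log_three_intercept(self):
        gamma = np.zeros((1, 18))
        gamma[0, 0] = np.log(3.0)
        params = LCRAParameters(gamma=gamma, beta=np.zeros((2, 2, 9)))
        np.testing.assert_allclose(
            class_membership_probs(np.zeros(17), params), [0.75, 0.25], atol=1e-12
        )

    def test_extreme_coefficients_stay_finite(self):
        gamma = np.full((2, 18), 50.0)
        params = LCRAParameters(gamma=gamma, beta=np.zeros((3, 2, 9)))
        probs = class_membership_probs(np.ones(17), params)
        assert np.all(np.isfinite(probs))
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_dimension_mismatch_raises(self, two_class_params):
        with pytest.raises(ValueError, match="columns"):
            class_membership_probs(np.zeros(5), two_class_params)


class TestOutcomeGivenClass:
    def test_zero_beta_uniform(self):
        params = LCRAParameters(gamma=np.zeros((1, 18)), beta=np.zeros((2, 2, 9)))
        np.testing.assert_allclose(
            outcome_probs_given_class(np.zeros(8), 0, params), [1 / 3] * 3, atol=1e-12
        )

    def test_intercept_only_closed_form(self):
        beta = np.zeros((1, 2, 9))
        beta[0, 0, 0] = np.log(2.0)  # non-violent vs no
        beta[0, 1, 0] = np.log(1.0)  # violent vs no
        params = LCRAParameters(gamma=np.zeros((0, 18)), beta=beta)
        np.testing.assert_allclose(
            outcome_probs_given_class(np.zeros(8), 0, params),
            [0.25, 0.50, 0.25],
            atol=1e-12,
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_softmax(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, K=2)
        row = rng.normal(size=8)
        for k in range(2):
            logits = [0.0] + [
                params.beta[k, c, 0] + params.beta[k, c, 1:] @ row for c in range(2)
            ]
            np.testing.assert_allclose(
                outcome_probs_given_class(row, k, params),
                brute_force_softmax(logits),
                atol=1e-12,
            )


class TestMixture:
    def test_single_class_collapses(self):
        rng = np.random.default_rng(1)
        params = random_params(rng, K=1)
        row_c, row_p = rng.normal(size=17), rng.normal(size=8)
        np.testing.assert_allclose(
            mixture_outcome_probs(row_c, row_p, params),
            outcome_probs_given_class(row_p, 0, params),
            atol=1e-14,
        )

    def test_half_half_mixture_arithmetic(self, two_class_params):
        # memberships (0.5, 0.5), class profiles (0.7,0.2,0.1) / (0.1,0.2,0.7)
        mix = mixture_outcome_probs(np.zeros(17), np.zeros(8), two_class_params)
        np.testing.assert_allclose(mix, [0.4, 0.2, 0.4], atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, K=3)
        row_c, row_p = rng.normal(size=17), rng.normal(size=8)
        pi = class_membership_probs(row_c, params)
        expected = np.zeros(3)
        for k in range(3):
            fk = outcome_probs_given_class(row_p, k, params)
            for c in range(3):
                expected[c] += pi[k] * fk[c]
        np.testing.assert_allclose(
            mixture_outcome_probs(row_c, row_p, params), expected, atol=1e-12
        )


class TestLogLikelihood:
    def test_single_case_half_probability(self, two_class_params):
        design = EncodedDesign(
            covariate_matrix=np.zeros((1, 17)),
            predictor_matrix=np.zeros((1, 8)),
            outcome_vector=np.array([1]),  # mixture prob of non-violent = 0.2
            covariate_names=[f"c{j}" for j in range(17)],
            predictor_names=[f"p{j}" for j in range(8)],
            reference_levels={},
        )
        assert log_likelihood(design, two_class_params) == pytest.approx(np.log(0.2))

    def test_matches_per_case_summation(self):
        rng = np.random.default_rng(5)
        params = random_params(rng, K=3)
        design = make_design(rng, params, n=10)
        expected = sum(
            np.log(
                mixture_outcome_probs(
                    design.covariate_matrix[i], design.predictor_matrix[i], params
                )[design.outcome_vector[i]]
            )
            for i in range(10)
        )
        assert log_likelihood(design, params) == pytest.approx(expected, abs=1e-10)

    def test_row_duplication_doubles_and_permutation_invariant(self):
        rng = np.random.default_rng(6)
        params = random_params(rng, K=2)
        design = make_design(rng, params, n=8)
        ll = log_likelihood(design, params)
        doubled = design.subset(np.r_[np.arange(8), np.arange(8)])
        assert log_likelihood(doubled, params) == pytest.approx(2 * ll, rel=1e-12)
        perm = design.subset(rng.permutation(8))
        assert log_likelihood(perm, params) == pytest.approx(ll, rel=1e-12)

    def test_missing_outcome_reports_ids(self):
        rng = np.random.default_rng(7)
        params = random_params(rng, K=2)
        design = make_design(rng, params, n=4, with_outcome=False)
        with pytest.raises(ValueError, match="outcome missing"):
            log_likelihood(design, params)


class TestPosteriors:
    def test_single_class_all_ones(self):
        rng = np.random.default_rng(8)
        params = random_params(rng, K=1)
        design = make_design(rng, params, n=5)
        post = posterior_class_probs(design, params)
        np.testing.assert_array_equal(post.probs, np.ones((5, 1)))

    def test_equal_prior_bayes_arithmetic(self, two_class_params):
        # observed outcome "no": class likelihoods 0.7 vs 0.1 -> (0.875, 0.125)
        design = EncodedDesign(
            covariate_matrix=np.zeros((1, 17)),
            predictor_matrix=np.zeros((1, 8)),
            outcome_vector=np.array([0]),
            covariate_names=[f"c{j}" for j in range(17)],
            predictor_names=[f"p{j}" for j in range(8)],
            reference_levels={},
        )
        post = posterior_class_probs(design, two_class_params)
        np.testing.assert_allclose(post.probs[0], [0.875, 0.125], atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_bayes(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, K=3)
        design = make_design(rng, params, n=6)
        post = posterior_class_probs(design, params).probs
        for i in range(6):
            pi = class_membership_probs(design.covariate_matrix[i], params)
            lik = np.array(
                [
                    outcome_probs_given_class(design.predictor_matrix[i], k, params)[
                        design.outcome_vector[i]
                    ]
                    for k in range(3)
                ]
            )
            expected = pi * lik / (pi * lik).sum()
            np.testing.assert_allclose(post[i], expected, atol=1e-12)

    def test_missing_outcome_reduces_to_prior(self):
        rng = np.random.default_rng(9)
        params = random_params(rng, K=3)
        design = make_design(rng, params, n=5, with_outcome=False)
        post = posterior_class_probs(design, params)
        np.testing.assert_allclose(
            post.probs,
            class_membership_probs(design.covariate_matrix, params),
            atol=1e-12,
        )

    def test_rows_normalized(self, two_class_params):
        rng = np.random.default_rng(10)
        design = make_design(rng, two_class_params, n=20)
        post = posterior_class_probs(design, two_class_params)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)


class TestClassSummaries:
    def test_class_sizes_mean_of_columns(self):
        from lcra.model import PosteriorMatrix

        post = PosteriorMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(class_sizes(post), [0.5, 0.5])

    def test_class_sizes_recover_generating_marginals(self, study_spec):
        from lcra import generate_cohort, encode

        records, labels = generate_cohort(
            dataclasses.replace(study_spec, n=5000, seed=31)
        )
        design = encode(records)
        post = posterior_class_probs(design, study_spec.params)
        true_freq = np.bincount(labels, minlength=3) / 5000
        np.testing.assert_allclose(class_sizes(post), true_freq, atol=0.03)

    def test_profile_uniform_when_beta_zero(self):
        params = LCRAParameters(gamma=np.zeros((0, 18)), beta=np.zeros((1, 2, 9)))
        rng = np.random.default_rng(11)
        design = make_design(rng, params, n=4)
        post = posterior_class_probs(design, params)
        prof = class_outcome_profile(design, params, post)
        np.testing.assert_allclose(prof, np.full((1, 3), 1 / 3), atol=1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_profile_matches_weighted_mean(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, K=3)
        design = make_design(rng, params, n=7)
        post = posterior_class_probs(design, params)
        prof = class_outcome_profile(design, params, post)
        for k in range(3):
            f = np.array(
                [
                    outcome_probs_given_class(design.predictor_matrix[i], k, params)
                    for i in range(7)
                ]
            )
            w = post.probs[:, k]
            np.testing.assert_allclose(prof[k], (w[:, None] * f).sum(0) / w.sum(), atol=1e-12)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-10)
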