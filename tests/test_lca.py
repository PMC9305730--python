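"""Latent class model: likelihood, EM updates, fitting and class ranking."""

import math

import numpy as np
import pytest

from qolclasses.errors import ConfigError
from qolclasses.lca import (
    LCAParameters,
    classify_modal,
    em_step,
    fit_em,
    loglikelihood,
    posterior,
    rank_classes_by_utility,
)

from conftest import (
    FOUR_CLASS_SEVERITIES,
    align_classes,
    brute_force_loglik,
    make_items,
    simulate_lca,
)


class TestLoglikelihood:
    def test_single_class_collapses_to_item_sum(self):
        rng = np.random.default_rng(0)
        values = rng.integers(1, 6, size=(8, 3))
        rho = rng.dirichlet(np.ones(5), size=(1, 3))
        params = LCAParameters(np.array([1.0]), rho, np.array([5, 5, 5]))
        expected = sum(
            math.log(rho[0, j, values[i, j] - 1])
            for i in range(8)
            for j in range(3)
        )
        assert loglikelihood(make_items(values), params) == pytest.approx(expected)

    def test_uniform_probabilities_closed_form(self):
        values = np.random.default_rng(1).integers(1, 6, size=(12, 20))
        rho = np.full((3, 20, 5), 0.2)
        params = LCAParameters(np.full(3, 1 / 3), rho, np.full(20, 5))
        assert loglikelihood(make_items(values), params) == pytest.approx(
            12 * 20 * math.log(0.2)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        N, J, K = rng.integers(2, 11), rng.integers(2, 5), rng.integers(1, 4)
        values = rng.integers(1, 5, size=(N, J))
        rho = rng.dirichlet(np.ones(4), size=(K, J))
        pi = rng.dirichlet(np.ones(K))
        params = LCAParameters(pi, rho, np.full(J, 4))
        got = loglikelihood(make_items(values, n_categories=4), params)
        want = brute_force_loglik(values, pi, rho)
        assert got == pytest.approx(want, abs=1e-9)

    def test_zero_probability_cell_warns_and_returns_neg_inf(self):
        values = np.array([[1, 1], [2, 2]])
        rho = np.zeros((1, 2, 5))
        rho[:, :, 2] = 1.0  # all mass on category 3, observed 1 and 2
        params = LCAParameters(np.array([1.0]), rho, np.array([5, 5]))
        with pytest.warns(RuntimeWarning, match="zero probability"):
            assert loglikelihood(make_items(values), params) == -np.inf

    def test_missing_data_is_rejected(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        items = make_items(np.ones((2, 2), int), mask=mask)
        params = LCAParameters(
            np.array([1.0]), np.full((1, 2, 5), 0.2), np.array([5, 5])
        )
        with pytest.raises(ConfigError):
            loglikelihood(items, params)


class TestEmStep:
    def test_mle_is_a_fixed_point_for_single_class(self):
        rng = np.random.default_rng(2)
        values = rng.integers(1, 6, size=(50, 3))
        items = make_items(values)
        freq = np.stack(
            [np.bincount(values[:, j] - 1, minlength=5) / 50 for j in range(3)]
        )[None]
        params = LCAParameters(np.array([1.0]), freq, np.array([5, 5, 5]))
        new, _ = em_step(items, params, floor=0.0)
        assert np.allclose(new.item_probs, params.item_probs, atol=1e-12)
        assert np.allclose(new.prevalences, params.prevalences, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_one_step_never_decreases_loglik(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 5, size=(40, 4))
        items = make_items(values, n_categories=4)
        rho = rng.dirichlet(np.ones(4) * 2, size=(2, 4))
        params = LCAParameters(np.array([0.3, 0.7]), rho, np.full(4, 4))
        before = loglikelihood(items, params)
        new, _ = em_step(items, params, floor=0.0)
        assert loglikelihood(items, new) >= before - 1e-9

    def test_two_person_two_class_posteriors_match_hand_calculation(self):
        # 2 binary items; person A answers (1,1), person B (2,2)
        values = np.array([[1, 1], [2, 2]])
        items = make_items(values, n_categories=2)
        rho = np.array(
            [[[0.8, 0.2], [0.8, 0.2]], [[0.3, 0.7], [0.3, 0.7]]]
        )
        params = LCAParameters(np.array([0.5, 0.5]), rho, np.array([2, 2]))
        gamma, _ = posterior(items, params)
        # person A: 0.5*0.64 vs 0.5*0.09 -> gamma = .64/.73
        assert gamma[0, 0] == pytest.approx(0.64 / 0.73)
        # person B: 0.5*0.04 vs 0.5*0.49 -> gamma = .04/.53
        assert gamma[1, 0] == pytest.approx(0.04 / 0.53)
        new, _ = em_step(items, params, floor=0.0)
        # M step: pi_1 = mean of gamma column 1
        assert new.prevalences[0] == pytest.approx(
            (0.64 / 0.73 + 0.04 / 0.53) / 2
        )


class TestFitEm:
    def test_single_class_fit_is_marginal_frequencies(self):
        rng = np.random.default_rng(3)
        values = rng.integers(1, 6, size=(200, 4))
        items = make_items(values)
        fit = fit_em(items, 1, seed=0, floor=0.0)
        for j in range(4):
            freq = np.bincount(values[:, j] - 1, minlength=5) / 200
            assert np.allclose(fit.params.item_probs[0, j], freq, atol=1e-12)
        assert fit.params.prevalences[0] == 1.0

    def test_same_seed_same_data_identical_result(self):
        items, *_ = simulate_lca([0.5, 0.5], FOUR_CLASS_SEVERITIES[[0, 3]], 300, seed=4)
        a = fit_em(items, 2, n_restarts=5, seed=11)
        b = fit_em(items, 2, n_restarts=5, seed=11)
        assert a.loglik == b.loglik
        assert np.array_equal(a.params.item_probs, b.params.item_probs)
        assert np.array_equal(a.posteriors, b.posteriors)

    def test_two_class_parameter_recovery(self):
        sev = np.array([[0.1] * 20, [0.7] * 20])
        items, truth, rho, pi = simulate_lca([0.4, 0.6], sev, 2000, seed=5)
        fit = fit_em(items, 2, n_restarts=10, seed=5)
        perm = align_classes(fit.params.item_probs, rho)
        assert np.abs(fit.params.prevalences[perm] - pi).max() < 0.03
        assert np.abs(fit.params.item_probs[perm] - rho).mean() < 0.05
        labels = classify_modal(fit.posteriors[:, perm])
        assert (labels == truth).mean() > 0.95

    def test_trace_is_monotone_up_to_floor_slack(self):
        items, *_ = simulate_lca(
            [0.25, 0.25, 0.25, 0.25], FOUR_CLASS_SEVERITIES, 600, seed=6
        )
        fit = fit_em(items, 4, n_restarts=3, seed=6)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-7 * (1 + np.abs(fit.loglik_trace[:-1]))).all()

    def test_information_criteria_closed_forms(self):
        items, *_ = simulate_lca(
            [0.25, 0.25, 0.25, 0.25], FOUR_CLASS_SEVERITIES, 200, seed=7
        )
        fit = fit_em(items, 4, n_restarts=3, seed=7)
        assert fit.n_params == 3 + 4 * 80  # (K-1) + K * sum(C_j - 1) = 323
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 323)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 323 * np.log(200))

    def test_label_permutation_leaves_indices_unchanged(self):
        items, *_ = simulate_lca([0.5, 0.5], FOUR_CLASS_SEVERITIES[[0, 3]], 200, seed=8)
        fit = fit_em(items, 2, n_restarts=3, seed=8)
        permuted = fit.params.permuted([1, 0])
        assert loglikelihood(items, permuted) == pytest.approx(fit.loglik, abs=1e-8)
        assert permuted.n_parameters() == fit.n_params


class TestClassifyAndRank:
    def test_modal_assignment_and_tie_break(self):
        post = np.array([[0.1, 0.7, 0.1, 0.1], [0.5, 0.5, 0.0, 0.0]])
        assert classify_modal(post).tolist() == [2, 1]

    def test_ranking_is_invariant_to_input_label_permutation(self):
        items, truth, *_ = simulate_lca(
            [0.25, 0.25, 0.25, 0.25], FOUR_CLASS_SEVERITIES, 800, seed=9
        )
        fit = fit_em(items, 4, n_restarts=5, seed=9)
        rng = np.random.default_rng(0)
        utilities = rng.random(800)
        pain = rng.random(800) * 100
        import dataclasses

        perm = [2, 0, 3, 1]
        shuffled = dataclasses.replace(
            fit, params=fit.params.permuted(perm), posteriors=fit.posteriors[:, perm]
        )
        a = rank_classes_by_utility(fit, utilities, pain_scores=pain)
        b = rank_classes_by_utility(shuffled, utilities, pain_scores=pain)
        assert np.allclose(a.params.item_probs, b.params.item_probs)
        assert np.allclose(a.posteriors, b.posteriors)

    def test_ranked_utilities_decrease(self, paper_cohort):
        fit = paper_cohort["fit"]
        util = paper_cohort["scores"].utility.to_numpy()
        labels = classify_modal(fit.posteriors)
        means = [util[labels == k].mean() for k in range(1, 5)]
        assert means[0] > means[-1]
        assert means == sorted(means, reverse=True)

    def test_k1_ranking_is_noop(self):
        items, *_ = simulate_lca([1.0], FOUR_CLASS_SEVERITIES[:1], 50, seed=10)
        fit = fit_em(items, 1, seed=0)
        ranked = rank_classes_by_utility(fit, np.random.default_rng(0).random(50))
        assert np.array_equal(ranked.params.item_probs, fit.params.item_probs)
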