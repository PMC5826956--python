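import numpy as np
import pytest
from scipy import optimize, special

from lcagrowth.lca_em import (
    PosteriorTable,
    _em_once,
    _final_loglik,
    _pattern_table,
    classification_table,
    fit_lca,
    modal_assignment,
    posterior_probs,
    relative_entropy,
)
from lcagrowth.model_spec import LcaParams, build_true_model, Condition
from lcagrowth.synthetic_data import generate_dataset

TOY_U = np.array(
    [
        [1, 1, 1, 1],
        [1, 1, 1, 0],
        [1, 0, 1, 1],
        [0, 0, 0, 1],
        [0, 0, 0, 0],
        [0, 1, 0, 0],
    ]
)


class TestFitLca:
    def test_one_class_closed_form(self, high_sep_dataset):
        u = high_sep_dataset.indicators
        fit, post = fit_lca(u, 1)
        from lcagrowth.model_spec import item_response_prob

        means = u.mean(axis=0)
        np.testing.assert_allclose(item_response_prob(fit.params.thresholds[0]), means)
        expected_ll = float(
            np.sum(u * np.log(means) + (1 - u) * np.log1p(-means))
        )
        assert fit.loglik == pytest.approx(expected_ll, abs=1e-8)
        assert fit.n_params == 4
        assert fit.bic == pytest.approx(-2 * expected_ll + 4 * np.log(len(u)), abs=1e-8)
        np.testing.assert_array_equal(post.probs, 1.0)

    def test_two_class_matches_direct_maximization(self):
        """EM reaches the same maximum as a multi-start direct optimizer."""

        def neg(z):
            pi2 = special.expit(z[0])
            p = np.clip(special.expit(z[1:]).reshape(2, 4), 1e-12, 1 - 1e-12)
            lf = (
                TOY_U @ np.log(p).T
                + (1 - TOY_U) @ np.log1p(-p).T
                + np.log([1 - pi2, pi2])
            )
            return -float(special.logsumexp(lf, axis=1).sum())

        rng = np.random.default_rng(0)
        oracle = min(
            optimize.minimize(neg, rng.normal(0, 2, 9), method="L-BFGS-B").fun
            for _ in range(30)
        )
        fit, _ = fit_lca(TOY_U, 2, n_starts=32, seed=1, tol=1e-10, max_iter=2000)
        assert fit.loglik == pytest.approx(-oracle, abs=1e-4)

    def test_high_separation_threshold_recovery(self):
        """Fitted thresholds recover +-1.750 within Monte-Carlo error."""
        model = build_true_model(Condition(2000, 0.30, "high"))
        reps = 20
        taus = np.empty((reps, 2, 4))
        for r in range(reps):
            ds = generate_dataset(model, 2000, seed=100 + r)
            fit, _ = fit_lca(ds.indicators, 2, seed=r)
            taus[r] = fit.params.thresholds  # class 1 is the larger class
        mean = taus.mean(axis=0)
        mc_se = taus.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean[0] - (-1.750)) < 3 * mc_se[0])
        assert np.all(np.abs(mean[1] - 1.750) < 3 * mc_se[1])

    def test_bic_prefers_two_classes_at_high_separation(self):
        model = build_true_model(Condition(2000, 0.30, "high"))
        wins = 0
        reps = 20
        for r in range(reps):
            ds = generate_dataset(model, 2000, seed=300 + r)
            b1 = fit_lca(ds.indicators, 1)[0].bic
            b2 = fit_lca(ds.indicators, 2, seed=r)[0].bic
            wins += b2 < b1
        assert wins >= int(0.95 * reps)

    def test_em_monotone_in_loglik(self):
        patterns, counts, _ = _pattern_table(TOY_U)
        rng = np.random.default_rng(5)
        pi0 = rng.dirichlet(np.ones(2))
        p0 = rng.uniform(0.1, 0.9, (2, 4))
        lls = [
            _em_once(patterns, counts, 2, pi0, p0, tol=0.0, max_iter=k)[2]
            for k in range(1, 14)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_label_permutation_leaves_loglik_and_entropy_unchanged(self, high_sep_dataset):
        u = high_sep_dataset.indicators
        fit, post = fit_lca(u, 2, seed=3)
        patterns, counts, _ = _pattern_table(u)
        params = fit.params
        ll_perm = _final_loglik(
            patterns, counts, params.mixing_props[::-1], params.item_probs[::-1]
        )
        assert ll_perm == pytest.approx(fit.loglik, abs=1e-8)
        swapped = PosteriorTable(post.probs[:, ::-1])
        assert relative_entropy(swapped) == pytest.approx(relative_entropy(post), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_lca(np.empty((0, 4), dtype=int), 1)
        with pytest.raises(ValueError):
            fit_lca(np.array([[1, 0, 1, 0], [1, 0, 1, 0]]), 2)  # one distinct pattern


class TestPosteriorProbs:
    def test_rows_normalized(self, high_sep_model, high_sep_dataset):
        post = posterior_probs(high_sep_model.lca, high_sep_dataset.indicators)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)

    def test_hand_bayes_example(self):
        params = LcaParams(2, [[-0.754] * 4, [0.754] * 4], [0.7, 0.3])
        post = posterior_probs(params, np.array([[1, 1, 1, 1]]))
        # p1 = 0.6801^4 * 0.7, p2 = 0.3199^4 * 0.3 -> 0.979 for class 1
        assert post.probs[0, 0] == pytest.approx(0.979, abs=5e-4)

    def test_indistinguishable_classes_give_uniform(self):
        params = LcaParams(2, np.zeros((2, 4)), [0.5, 0.5])
        post = posterior_probs(params, TOY_U)
        np.testing.assert_allclose(post.probs, 0.5, atol=1e-14)


class TestModalAssignment:
    def test_argmax_and_tie_break(self):
        post = PosteriorTable(np.array([[0.2, 0.8], [0.5, 0.5], [1.0, 0.0]]))
        np.testing.assert_array_equal(modal_assignment(post), [2, 1, 1])

    def test_identity_posteriors_recover_truth(self, high_sep_dataset):
        n = 50
        labels = high_sep_dataset.true_class[:n]
        probs = np.zeros((n, 2))
        probs[np.arange(n), labels - 1] = 1.0
        assert np.array_equal(modal_assignment(PosteriorTable(probs)), labels)


class TestClassificationTable:
    def test_perfect_classification_gives_identity(self):
        probs = np.zeros((10, 2))
        probs[:6, 0] = 1.0
        probs[6:, 1] = 1.0
        post = PosteriorTable(probs)
        tab = classification_table(post, modal_assignment(post))
        np.testing.assert_allclose(tab.q, np.eye(2), atol=1e-12)
        np.testing.assert_array_equal(tab.assigned_counts, [6, 4])

    def test_hand_arithmetic(self):
        post = PosteriorTable(np.array([[0.8, 0.2], [0.6, 0.4]]))
        W = modal_assignment(post)
        np.testing.assert_array_equal(W, [1, 1])
        tab = classification_table(post, W)
        np.testing.assert_allclose(tab.q, [[1.0, 0.0], [1.0, 0.0]], atol=1e-12)

    def test_rows_sum_to_one_and_diagonal_dominant_at_high_separation(
        self, high_sep_dataset
    ):
        fit, post = fit_lca(high_sep_dataset.indicators, 2, seed=9)
        tab = classification_table(post, modal_assignment(post))
        np.testing.assert_allclose(tab.q.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diag(tab.q)[:, None] >= tab.q - np.diag(np.diag(tab.q)))

    def test_zero_mass_class_errors(self):
        post = PosteriorTable(np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            classification_table(post, np.array([1, 1]))


class TestRelativeEntropy:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            (np.array([[1.0, 0.0], [0.0, 1.0]]), 1.0),
            (np.array([[0.5, 0.5], [0.5, 0.5]]), 0.0),
            (np.array([[1.0, 0.0], [0.5, 0.5]]), 0.5),
        ],
    )
    def test_examples(self, probs, expected):
        assert relative_entropy(PosteriorTable(probs)) == pytest.approx(expected, abs=1e-12)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            relative_entropy(PosteriorTable(np.ones((3, 1))))

    def test_bounds(self, rng):
        raw = rng.dirichlet(np.ones(3), size=40)
        e = relative_entropy(PosteriorTable(raw))
        assert 0.0 <= e <= 1.0
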