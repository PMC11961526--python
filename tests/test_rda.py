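"""Regularized discriminant analysis: splitting, fitting, prediction,
tuning, and agreement with independent Gaussian-density oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from osteorda import fit_rda, predict_rda, stratified_split, tune_rda


def _gaussian_blobs(rng, n_per_class=30, p=4, n_classes=3, spread=3.0):
    X, y = [], []
    for k in range(n_classes):
        mean = rng.normal(scale=spread, size=p)
        A = rng.normal(size=(p, p)) * 0.4
        cov = A @ A.T + np.eye(p)
        X.append(rng.multivariate_normal(mean, cov, size=n_per_class))
        y.extend([f"c{k}"] * n_per_class)
    return np.vstack(X), np.array(y)


class TestStratifiedSplit:
    def test_two_strata_of_five_give_one_test_each(self):
        labels = ["a"] * 5 + ["b"] * 5
        plan = stratified_split(labels, test_fraction=0.2, seed=0)
        assert len(plan.train_ids) == 8 and len(plan.test_ids) == 2
        assert sum(1 for i in plan.test_ids if i < 5) == 1

    def test_same_seed_identical_plan(self):
        labels = ["a"] * 12 + ["b"] * 9
        p1 = stratified_split(labels, seed=7)
        p2 = stratified_split(labels, seed=7)
        assert p1.train_ids == p2.train_ids and p1.test_ids == p2.test_ids

    def test_disjoint_and_exhaustive(self):
        labels = ["a"] * 13 + ["b"] * 8 + ["c"] * 21
        plan = stratified_split(labels, seed=3)
        ids = sorted(plan.train_ids + plan.test_ids)
        assert ids == list(range(len(labels)))

    def test_empirical_fraction_concentrates_near_target(self):
        labels = ["a"] * 25 + ["b"] * 25
        fracs = [
            len(stratified_split(labels, test_fraction=0.2, seed=s).test_ids) / 50
            for s in range(300)
        ]
        assert abs(np.mean(fracs) - 0.2) < 0.02

    def test_tiny_stratum_warns_into_train_or_raises(self):
        labels = ["a"] * 10 + ["solo"]
        with pytest.warns(UserWarning, match="solo"):
            plan = stratified_split(labels, seed=0)
        assert 10 in plan.train_ids
        with pytest.raises(ValueError):
            stratified_split(labels, seed=0, small_stratum="fatal")


class TestFitLimits:
    def test_lambda_one_gamma_zero_is_pooled_lda(self, rng):
        X, y = _gaussian_blobs(rng)
        model = fit_rda(X, y, lam=1.0, gamma=0.0)
        for k in range(model.n_classes):
            np.testing.assert_allclose(model.reg_covs[k], model.pooled_cov)

    def test_gamma_one_gives_spherical_covariances(self, rng):
        X, y = _gaussian_blobs(rng)
        model = fit_rda(X, y, lam=0.3, gamma=1.0)
        for k in range(model.n_classes):
            cov = model.reg_covs[k]
            np.testing.assert_allclose(cov, np.eye(len(cov)) * cov[0, 0], atol=1e-12)

    def test_qda_limit_recovers_sample_covariances(self, rng):
        X, y = _gaussian_blobs(rng)
        model = fit_rda(X, y, lam=0.0, gamma=0.0)
        for k, c in enumerate(model.classes):
            np.testing.assert_allclose(
                model.reg_covs[k], np.cov(X[y == c], rowvar=False), atol=1e-10
            )

    def test_invalid_hyperparameters_rejected(self, rng):
        X, y = _gaussian_blobs(rng)
        with pytest.raises(ValueError):
            fit_rda(X, y, lam=1.5, gamma=0.0)


class TestPredict:
    def test_one_dimensional_midpoint_boundary(self, rng):
        X = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 200)])[:, None]
        y = np.array(["one"] * 200 + ["two"] * 200)
        model = fit_rda(X, y, lam=1.0, gamma=0.0, priors="uniform")
        lo, _, _ = predict_rda(model, np.array([[0.9]]))
        hi, _, _ = predict_rda(model, np.array([[1.1]]))
        # sample means are near 0 and 2, so the LDA boundary sits near 1
        mid = model.means.mean()
        assert abs(mid - 1.0) < 0.2
        assert lo[0] == "one" and hi[0] == "two"

    def test_posteriors_sum_to_one_and_priors_shift_invariance(self, rng):
        X, y = _gaussian_blobs(rng)
        m1 = fit_rda(X, y, 0.5, 0.25, priors=np.array([1.0, 2.0, 3.0]))
        m3 = fit_rda(X, y, 0.5, 0.25, priors=np.array([3.0, 6.0, 9.0]))
        l1, p1, _ = predict_rda(m1, X)
        l3, p3, _ = predict_rda(m3, X)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-8)
        assert (l1 == l3).all()

    def test_labels_match_brute_force_gaussian_densities(self, rng):
        """QDA decisions agree with direct density evaluation per class."""
        X, y = _gaussian_blobs(rng, n_per_class=40, p=4)
        model = fit_rda(X, y, lam=0.0, gamma=0.0)
        labels, _, _ = predict_rda(model, X)
        counts = {c: (y == c).sum() for c in model.classes}
        oracle_scores = np.column_stack(
            [
                multivariate_normal(model.means[k], model.reg_covs[k]).logpdf(X)
                + np.log(counts[c] / len(y))
                for k, c in enumerate(model.classes)
            ]
        )
        oracle = np.array([model.classes[i] for i in oracle_scores.argmax(axis=1)])
        assert (labels == oracle).all()

    def test_translation_of_features_leaves_predictions_unchanged(self, rng):
        X, y = _gaussian_blobs(rng)
        shift = rng.normal(size=X.shape[1]) * 10
        m0 = fit_rda(X, y, 0.5, 0.1)
        m1 = fit_rda(X + shift, y, 0.5, 0.1)
        l0, p0, _ = predict_rda(m0, X)
        l1, p1, _ = predict_rda(m1, X + shift)
        assert (l0 == l1).all()
        np.testing.assert_allclose(p0, p1, atol=1e-8)

    def test_adding_constant_to_scores_preserves_decisions(self, rng):
        X, y = _gaussian_blobs(rng)
        model = fit_rda(X, y, 0.75, 0.25)
        labels, _, scores = predict_rda(model, X)
        shifted = scores + 123.456
        relabeled = np.array([model.classes[i] for i in shifted.argmax(axis=1)])
        assert (labels == relabeled).all()

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _gaussian_blobs(rng)
        model = fit_rda(X, y, 1.0, 0.0)
        with pytest.raises(ValueError):
            predict_rda(model, X[:, :2])

    def test_lda_limit_matches_closed_form_linear_discriminant(self):
        """At (lambda=1, gamma=0) decisions equal the closed-form linear rule
        w_k = S^-1 mu_k, b_k = -mu_k' S^-1 mu_k / 2 + log pi_k, computed
        independently, across 20 random small instances."""
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            X, y = _gaussian_blobs(rng, n_per_class=15, p=3, n_classes=3)
            model = fit_rda(X, y, lam=1.0, gamma=0.0)
            labels, _, _ = predict_rda(model, X)

            # independent closed form from raw data
            classes = sorted(set(y))
            mus = np.array([X[y == c].mean(axis=0) for c in classes])
            pooled = sum(
                (X[y == c] - mu).T @ (X[y == c] - mu) for c, mu in zip(classes, mus)
            ) / (len(X) - len(classes))
            pis = np.array([(y == c).mean() for c in classes])
            W = np.linalg.solve(pooled, mus.T)  # (p, K)
            b = -0.5 * np.sum(mus.T * W, axis=0) + np.log(pis)
            lin = X @ W + b
            oracle = np.array([classes[i] for i in lin.argmax(axis=1)])
            assert (labels == oracle).all(), f"trial {trial}"


class TestTune:
    def test_degenerate_grid_returned(self, rng):
        X, y = _gaussian_blobs(rng)
        best, table = tune_rda(X, y, grid=[(1.0, 0.0)], k=5, seed=0)
        assert best == (1.0, 0.0) and len(table) == 1

    def test_same_seed_identical_cv_table(self, rng):
        X, y = _gaussian_blobs(rng)
        grid = [(0.0, 0.1), (0.5, 0.1), (1.0, 0.1)]
        _, t1 = tune_rda(X, y, grid=grid, k=5, seed=9)
        _, t2 = tune_rda(X, y, grid=grid, k=5, seed=9)
        assert t1.equals(t2)

    def test_empty_grid_rejected(self, rng):
        X, y = _gaussian_blobs(rng)
        with pytest.raises(ValueError):
            tune_rda(X, y, grid=[])

    def test_fold_count_reduced_for_small_classes(self, rng):
        X, y = _gaussian_blobs(rng, n_per_class=6)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            tune_rda(X, y, grid=[(1.0, 0.1)], k=10, seed=0)

    def test_shared_covariance_data_selects_high_lambda(self):
        """When classes truly share a covariance, CV should prefer the
        pooled (LDA-like) end of the grid in most runs."""
        wins = 0
        n_runs = 50
        for s in range(n_runs):
            rng = np.random.default_rng(5000 + s)
            cov = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.3], [0.1, 0.3, 1.0]])
            X = np.vstack(
                [rng.multivariate_normal(mu, cov, size=20) for mu in
                 ([0, 0, 0], [1.5, 0.5, 0], [0, 1.5, 1.0])]
            )
            y = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
            (lam, _), _ = tune_rda(X, y, k=5, seed=s)
            wins += lam >= 0.5
        assert wins >= 0.8 * n_runs, wins
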