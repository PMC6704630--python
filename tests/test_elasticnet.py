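"""Solver correctness against an independent optimizer, and its
structural invariants (null model, grouped sparsity, permutation
equivariance, prediction normalization)."""

import warnings

import numpy as np
import pytest

from immunosig.elasticnet import (
    ElasticNetLogistic,
    cross_validate,
    elastic_net_objective,
    fit_binary_elasticnet,
    fit_multinomial_elasticnet,
    lambda_max,
)
from immunosig.errors import ValidationError
from immunosig.model import PenaltySpec
from oracles import optimize_elastic_net

PAPER_GRID = [0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001]


def _instance(seed, n=8, p=4, k=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    y = np.array([i % k for i in range(n)])
    return X, y


class TestObjectiveAgainstGenericOptimizer:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.93, 1.0])
    @pytest.mark.parametrize("grouped", [True, False])
    def test_multinomial_three_class(self, alpha, grouped):
        X, y = _instance(1)
        est = ElasticNetLogistic(
            alpha=alpha, lam=0.05, grouped=grouped, standardize=False,
            mode="multinomial", tol=1e-13, max_iter=200_000,
        ).fit(X, y)
        mine = elastic_net_objective(
            X, y, est.intercept_, est.coef_.T, alpha, 0.05,
            grouped=grouped, kind="multinomial", class_labels=est.classes_,
        )
        oracle = optimize_elastic_net(
            X, y, alpha, 0.05, grouped, "multinomial",
            warm=(est.intercept_, est.coef_.T),
        )
        assert abs(mine - oracle) <= 1e-6

    @pytest.mark.parametrize("alpha", [0.0, 0.93])
    def test_binary(self, alpha):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (8, 2))
        y = np.array([0, 1] * 4)
        est = ElasticNetLogistic(
            alpha=alpha, lam=0.03, standardize=False, mode="binary",
            tol=1e-13, max_iter=200_000,
        ).fit(X, y)
        mine = elastic_net_objective(
            X, y, est.intercept_, est.coef_.T, alpha, 0.03,
            grouped=False, kind="binary", class_labels=est.classes_,
        )
        oracle = optimize_elastic_net(
            X, y, alpha, 0.03, False, "binary", warm=(est.intercept_, est.coef_.T)
        )
        assert abs(mine - oracle) <= 1e-6


class TestNullModelLimit:
    def test_lambda_above_max_gives_intercept_only_multinomial(self):
        X, y = _instance(3, n=12, p=5, k=3)
        lmax = lambda_max(X, y, alpha=0.93, grouped=True, standardize=True)
        est = ElasticNetLogistic(alpha=0.93, lam=lmax * 1.01, mode="multinomial").fit(X, y)
        assert np.all(est.coef_ == 0.0)
        # intercept differences equal class log-frequency differences
        freqs = np.array([(y == c).mean() for c in est.classes_])
        diff = est.intercept_ - np.log(freqs)
        assert np.allclose(diff, diff[0], atol=1e-6)

    def test_lambda_above_max_binary_intercept_is_log_odds(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (10, 3))
        y = np.array([0] * 6 + [1] * 4)
        lmax = lambda_max(X, y, alpha=0.93, kind="binary")
        est = ElasticNetLogistic(alpha=0.93, lam=lmax * 1.01, mode="binary",
                                 tol=1e-12).fit(X, y)
        assert np.all(est.coef_ == 0.0)
        assert est.intercept_[0] == pytest.approx(np.log(0.4 / 0.6), abs=1e-6)

    def test_objective_never_worse_than_null_model(self):
        X, y = _instance(5, n=10, p=6)
        for lam in [0.2, 0.01]:
            est = ElasticNetLogistic(lam=lam, standardize=False, mode="multinomial",
                                     tol=1e-10).fit(X, y)
            fitted = est.objective_
            null = ElasticNetLogistic(lam=lam, standardize=False, mode="multinomial",
                                      tol=1e-10)
            lmax = lambda_max(X, y, 0.93, standardize=False)
            null.lam = max(lam, lmax * 1.1)
            null.fit(X, y)
            null_obj = elastic_net_objective(
                X, y, null.intercept_, null.coef_.T, 0.93, lam,
                kind="multinomial", class_labels=null.classes_,
            )
            assert fitted <= null_obj + 1e-9


class TestGroupedSparsityStructure:
    def test_genes_zeroed_whole_rows_only(self):
        X, y = _instance(6, n=15, p=10, k=3)
        est = ElasticNetLogistic(alpha=0.93, lam=0.05, grouped=True,
                                 mode="multinomial").fit(X, y)
        B = est.coef_.T  # (p, K)
        row_nonzero = np.any(B != 0.0, axis=1)
        for j in range(B.shape[0]):
            if row_nonzero[j]:
                assert np.all(B[j] != 0.0) or np.linalg.norm(B[j]) > 0
            else:
                assert np.all(B[j] == 0.0)
        # at this lambda some but not all genes survive
        assert 0 < row_nonzero.sum() < B.shape[0]

    def test_nonzero_count_non_increasing_along_grid(self):
        X, y = _instance(7, n=30, p=20, k=3)
        est = ElasticNetLogistic(alpha=0.93, grouped=True, mode="multinomial",
                                 tol=1e-9)
        fits = est.path(X, y, PAPER_GRID)
        nnz = [f["n_nonzero_genes"] for f in fits]
        assert all(a <= b for a, b in zip(nnz, nnz[1:])), nnz


class TestEquivariance:
    def test_sample_permutation_changes_nothing(self):
        X, y = _instance(8, n=12, p=6)
        est1 = ElasticNetLogistic(lam=0.02, mode="multinomial", tol=1e-10).fit(X, y)
        perm = np.random.default_rng(0).permutation(12)
        est2 = ElasticNetLogistic(lam=0.02, mode="multinomial", tol=1e-10).fit(X[perm], y[perm])
        assert np.allclose(est1.coef_, est2.coef_, atol=1e-9)
        assert np.allclose(est1.intercept_, est2.intercept_, atol=1e-9)

    def test_gene_permutation_permutes_coefficients(self):
        X, y = _instance(9, n=12, p=6)
        est1 = ElasticNetLogistic(lam=0.02, mode="multinomial", tol=1e-10).fit(X, y)
        perm = np.random.default_rng(1).permutation(6)
        est2 = ElasticNetLogistic(lam=0.02, mode="multinomial", tol=1e-10).fit(X[:, perm], y)
        assert np.allclose(est1.coef_[:, perm], est2.coef_, atol=1e-9)


class TestPrediction:
    def test_separable_toy_reaches_perfect_accuracy(self):
        X = np.array([[-1.0], [-0.9], [1.0], [0.9]])
        y = np.array([0, 0, 1, 1])
        est = ElasticNetLogistic(alpha=0.93, lam=1e-4, mode="binary").fit(X, y)
        assert np.array_equal(est.predict(X), y)

    def test_probability_rows_sum_to_one(self):
        X, y = _instance(10, n=12, p=5)
        est = ElasticNetLogistic(lam=0.01, mode="multinomial").fit(X, y)
        P = est.predict_proba(np.random.default_rng(2).normal(0, 1, (7, 5)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_score_shift_invariance(self):
        X, y = _instance(11, n=9, p=4)
        model = fit_multinomial_elasticnet(X, y, PenaltySpec(lam=0.05))
        P1 = model.predict_proba(X)
        model.intercepts = model.intercepts + 3.7
        P2 = model.predict_proba(X)
        assert np.allclose(P1, P2, atol=1e-12)

    def test_zero_coefficient_model_predicts_prior(self):
        X, y = _instance(12, n=12, p=4)
        lmax = lambda_max(X, y, 0.93)
        model = fit_multinomial_elasticnet(X, y, PenaltySpec(lam=lmax * 1.5))
        P = model.predict_proba(np.random.default_rng(3).normal(0, 1, (5, 4)))
        expected = np.exp(model.intercepts) / np.exp(model.intercepts).sum()
        assert np.allclose(P, expected, atol=1e-9)


class TestCrossValidate:
    def test_deterministic_given_seed(self):
        X, y = _instance(13, n=24, p=8, k=3)
        spec = PenaltySpec(lam=0.01, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv1 = cross_validate(X, y, [0.1, 0.01], spec, nfolds=4, seed=5)
            cv2 = cross_validate(X, y, [0.1, 0.01], spec, nfolds=4, seed=5)
        assert np.array_equal(cv1["mean_deviance"], cv2["mean_deviance"])

    def test_null_lambda_no_better_than_best(self):
        X, y = _instance(14, n=30, p=10, k=3)
        # make the problem learnable so the CV curve is informative
        X[:, 0] += (y == 0) * 2.0
        X[:, 1] += (y == 1) * 2.0
        spec = PenaltySpec(lam=0.01, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cross_validate(X, y, [5.0, 0.05, 0.01], spec, nfolds=5, seed=3)
        dev = cv["mean_deviance"]
        assert dev[0] >= dev.min() - 1e-9

    def test_empty_grid_rejected(self):
        X, y = _instance(15)
        with pytest.raises(ValidationError, match="empty"):
            cross_validate(X, y, [], PenaltySpec(lam=0.1))

    def test_small_class_degrades_with_warning(self):
        X, y = _instance(16, n=9, p=3, k=3)
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validate(X, y, [0.1], PenaltySpec(lam=0.1), nfolds=10, seed=0)


class TestValidation:
    def test_single_class_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValidationError, match="two classes"):
            ElasticNetLogistic().fit(X, np.zeros(4))

    def test_binary_wrapper_spec_round_trip(self):
        rng = np.random.default_rng(20)
        X = rng.normal(0, 1, (10, 3))
        y = np.array([0, 1] * 5)
        model = fit_binary_elasticnet(X, y, PenaltySpec(alpha=0.5, lam=0.07))
        assert model.kind == "binary"
        assert model.penalty.alpha == 0.5
        assert model.coefficients.shape == (3, 1)
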