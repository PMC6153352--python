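import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression

from pvsignal import (
    CislResult,
    LassoPath,
    bic_select,
    cisl,
    default_lambda_grid,
    lambda_max,
    lasso_logistic_path,
)
from pvsignal.penalized_regression import qualifying_size_counts


def _logistic_data(n, p, beta, intercept, seed, prevalence=0.3):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < prevalence).astype(float)
    probs = expit(intercept + X @ beta)
    y = (rng.random(n) < probs).astype(float)
    return y, X


class TestLassoPath:
    def test_full_shrinkage_limit(self):
        y, X = _logistic_data(300, 3, np.array([1.0, -0.5, 0.0]), -0.5, seed=0)
        lmax = lambda_max(y, X)
        path = lasso_logistic_path(y, X, lambdas=np.array([10 * lmax, 2 * lmax]))
        assert path.active_set(0) == ()
        assert path.active_set(1) == ()
        assert path.intercepts[0] == pytest.approx(logit(y.mean()), abs=1e-3)

    def test_lambda_zero_equals_unpenalized_fit(self):
        y, X = _logistic_data(200, 3, np.array([0.8, -0.6, 0.3]), -0.3, seed=1)
        lmax = lambda_max(y, X)
        path = lasso_logistic_path(y, X, lambdas=np.array([lmax, 0.0]))
        ref = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10, max_iter=5000)
        ref.fit(X, y)
        assert np.allclose(path.coefs[-1], ref.coef_[0], atol=1e-4)
        assert path.intercepts[-1] == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_single_covariate_matches_coordinate_descent_oracle(self):
        """Penalized solution equals an exact soft-thresholded Newton/CD oracle."""

        def cd_oracle(y, x, lam, iters=3000):
            b0, b1 = logit(y.mean()), 0.0
            for _ in range(iters):
                p = expit(b0 + b1 * x)
                b0 += np.sum(y - p) / np.sum(p * (1 - p))
                p = expit(b0 + b1 * x)
                g = np.sum(x * (y - p))
                h = np.sum(x * x * p * (1 - p))
                z = h * b1 + g
                b1 = np.sign(z) * max(abs(z) - lam, 0.0) / h
            return b0, b1

        y, X = _logistic_data(400, 1, np.array([1.1]), -1.0, seed=2)
        x = X[:, 0]
        lmax = lambda_max(y, X)
        grid = np.geomspace(lmax * 0.7, 0.02 * lmax, 8)
        path = lasso_logistic_path(y, X, lambdas=grid, tol=1e-10, max_iter=20000)
        for k, lam in enumerate(grid):
            b0, b1 = cd_oracle(y, x, lam)
            assert path.coefs[k, 0] == pytest.approx(b1, abs=5e-4)
            assert path.intercepts[k] == pytest.approx(b0, abs=5e-4)

    def test_active_set_weakly_grows_down_the_path(self, small_db):
        rm = small_db.rm
        y = rm.ae_column(0)
        path = lasso_logistic_path(y, rm.X.astype(float))
        sizes = [len(s) for s in path.active_sets()]
        # allow churn of one covariate between consecutive grid points
        assert all(b >= a - 1 for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] == 0  # empty model at lambda_max

    def test_single_class_outcome_raises(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="single class"):
            lasso_logistic_path(np.zeros(10), X)

    def test_grid_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            LassoPath(
                lambdas=np.array([1.0, 2.0]),
                coefs=np.zeros((2, 1)),
                intercepts=np.zeros(2),
            )


class TestBicSelect:
    def test_bic_formula_against_closed_form_null_model(self):
        rng = np.random.default_rng(4)
        y = (rng.random(500) < 0.2).astype(float)
        X = (rng.random((500, 3)) < 0.3).astype(float)
        lmax = lambda_max(y, X)
        path = lasso_logistic_path(y, X, lambdas=np.array([2 * lmax, lmax / 2]))
        sel = bic_select(path, y, X)
        n, k = len(y), y.sum()
        ll_null = k * np.log(k / n) + (n - k) * np.log(1 - k / n)
        bic_null = -2 * ll_null + 1 * np.log(n)
        assert sel.candidates[()] == pytest.approx(bic_null, rel=1e-9)

    def test_intercept_only_fallback_when_nothing_helps(self):
        rng = np.random.default_rng(5)
        y = (rng.random(800) < 0.1).astype(float)
        X = (rng.random((800, 5)) < 0.3).astype(float)  # pure noise
        path = lasso_logistic_path(y, X)
        sel = bic_select(path, y, X)
        assert sel.selected == () or len(sel.selected) <= 1

    def test_recovers_strong_true_effects(self):
        """5 strong effects among 50 covariates, n=5000: the BIC winner always
        contains the true set, and equals it exactly in most replicates (the
        occasional extra covariate is the max-correlated noise column, whose
        selection-biased deviance gain sometimes beats the ln(n) penalty)."""
        exact, superset, extras = 0, 0, []
        n_seeds = 20
        for seed in range(n_seeds):
            beta = np.zeros(50)
            beta[:5] = 1.2
            y, X = _logistic_data(5000, 50, beta, -2.5, seed=100 + seed, prevalence=0.1)
            path = lasso_logistic_path(y, X)
            sel = bic_select(path, y, X)
            exact += sel.selected == (0, 1, 2, 3, 4)
            superset += set(range(5)) <= set(sel.selected)
            extras.append(len(sel.selected) - 5)
        assert superset == n_seeds
        assert exact >= 0.6 * n_seeds
        assert np.mean(extras) <= 1.0

    def test_known_arithmetic_example(self):
        # -2(-100) + 2 ln 1000 = 213.82 beats -2(-98) + 3 ln 1000 = 216.72
        bic2 = -2 * (-100.0) + 2 * np.log(1000)
        bic3 = -2 * (-98.0) + 3 * np.log(1000)
        assert bic2 == pytest.approx(213.82, abs=0.005)
        assert bic3 == pytest.approx(216.72, abs=0.005)
        assert bic2 < bic3


def _path_from_coefs(coef_rows):
    coefs = np.array(coef_rows, dtype=float)
    lambdas = np.geomspace(1.0, 0.01, len(coefs))
    return LassoPath(lambdas=lambdas, coefs=coefs, intercepts=np.zeros(len(coefs)))


class TestCisl:
    def test_pi_hat_counts_distinct_model_sizes(self):
        """Covariate positive at model sizes {1, 2} with E = 4 scores 0.5."""
        path = _path_from_coefs(
            [
                [0.5, 0.0, 0.0, 0.0, 0.0],  # eta = 1
                [0.4, -0.2, 0.0, 0.0, 0.0],  # eta = 2
                [-0.1, -0.2, 0.3, 0.0, 0.0],  # eta = 3, covariate 0 now negative
                [-0.1, -0.2, 0.3, 0.1, 0.0],  # eta = 4
            ]
        )
        hits, largest = qualifying_size_counts(path, "positive")
        assert largest == 4
        pi = hits / largest
        assert pi[0] == 0.5  # sizes {1, 2}
        assert pi[1] == 0.0  # never positive
        assert pi[2] == 0.5  # sizes {3, 4}
        assert pi[4] == 0.0  # never active
        hits_nz, _ = qualifying_size_counts(path, "nonzero")
        assert hits_nz[0] == 4 * 1.0  # active at every size
        assert hits_nz[1] == 3

    def test_always_and_never_selected_covariates(self):
        beta = np.zeros(10)
        beta[0] = 2.0
        y, X = _logistic_data(3000, 10, beta, -2.0, seed=6, prevalence=0.2)
        res = cisl(y, X, B=20, seed=0)
        assert res.pi_hat.shape == (10, 20)
        assert (res.pi_hat >= 0).all() and (res.pi_hat <= 1).all()
        assert (res.pi_hat[0] > 0).all()  # the driver appears in every subsample
        assert 0 in res.selected(0.05) and 0 in res.selected(0.10)
        # covariates that never enter any model are never selected
        never = np.flatnonzero((res.pi_hat == 0).all(axis=1))
        for i in never:
            assert i not in res.selected(0.10)

    def test_quantile_nesting_smaller_q_is_stricter(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pi = rng.random((6, 40)) * (rng.random((6, 40)) < 0.7)
            res = CislResult(pi_hat=pi, E=5, sign_constraint="positive")
            assert set(res.selected(0.05)) <= set(res.selected(0.10))
            assert set(res.selected(0.10)) <= set(res.selected(0.25))

    def test_fixed_seed_bit_reproducible(self):
        beta = np.zeros(6)
        beta[0] = 1.5
        y, X = _logistic_data(1500, 6, beta, -2.0, seed=8, prevalence=0.2)
        a = cisl(y, X, B=10, seed=3)
        b = cisl(y, X, B=10, seed=3)
        assert np.array_equal(a.pi_hat, b.pi_hat)
        assert a.E == b.E

    def test_case_upweighting_raises_case_fraction(self):
        from pvsignal.penalized_regression import _case_weighted_probs

        rng = np.random.default_rng(9)
        y = (rng.random(5000) < 0.02).astype(float)
        probs = _case_weighted_probs(y, target_case_fraction=0.25)
        case_mass = probs[y > 0].sum()
        assert case_mass == pytest.approx(0.25, abs=0.01)

    def test_nonzero_constraint_is_weaker_than_positive(self):
        beta = np.zeros(8)
        beta[0], beta[1] = 1.5, -1.5
        y, X = _logistic_data(2500, 8, beta, -1.5, seed=10, prevalence=0.2)
        pos = cisl(y, X, B=15, sign_constraint="positive", seed=1)
        nz = cisl(y, X, B=15, sign_constraint="nonzero", seed=1)
        assert (nz.pi_hat >= pos.pi_hat - 1e-12).all()
        assert set(pos.selected(0.10)) <= set(nz.selected(0.10))

    def test_bad_inputs(self):
        y, X = _logistic_data(100, 2, np.zeros(2), 0.0, seed=11)
        with pytest.raises(ValueError, match="B=2"):
            cisl(y, X, B=1)
        with pytest.raises(ValueError, match="sign constraint"):
            cisl(y, X, B=2, sign_constraint="negative")
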