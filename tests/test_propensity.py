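import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import expit

from pvsignal import (
    PropensityScore,
    ReportMatrix,
    hdps_bias_scores,
    ps_bic,
    ps_cisl,
    ps_gtb,
    ps_hdps,
)
from pvsignal.propensity_estimation import PS_CLAMP, PsCache


def _rm_from_X(X, y=None, seed=0):
    n = X.shape[0]
    if y is None:
        y = (np.random.default_rng(seed).random(n) < 0.1).astype(int)
    return ReportMatrix(
        X=sp.csr_matrix(X.astype(int)),
        Y=sp.csr_matrix(np.asarray(y).reshape(-1, 1)),
        drug_ids=[f"D{k}" for k in range(X.shape[1])],
        ae_ids=["e"],
    )


def _independent_rm(n=8000, p=10, prev=0.1, seed=0):
    rng = np.random.default_rng(seed)
    return _rm_from_X((rng.random((n, p)) < prev).astype(int), seed=seed)


def _driven_rm(n=10000, seed=0):
    """Exposure of drug 0 driven by drugs 1-3; drugs 4-9 are noise."""
    rng = np.random.default_rng(seed)
    Z = (rng.random((n, 9)) < 0.25).astype(int)
    probs = expit(-2.5 + 1.2 * Z[:, 0] + 1.0 * Z[:, 1] + 0.9 * Z[:, 2])
    x = (rng.random(n) < probs).astype(int)
    X = np.column_stack([x, Z])
    return _rm_from_X(X, seed=seed), probs


class TestPsBic:
    def test_independent_exposure_gives_constant_ps(self):
        rm = _independent_rm(seed=1)
        ps = ps_bic(rm, 0)
        prev = rm.drug_column(0).mean()
        assert ps.covariates_used == ()
        assert np.allclose(ps.scores, prev, atol=1e-9)

    def test_recovers_exposure_drivers(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rm, _ = _driven_rm(seed=seed)
            ps = ps_bic(rm, 0)
            hits += {1, 2, 3} <= set(ps.covariates_used)
        assert hits >= 0.9 * n_seeds

    def test_scores_equal_inverse_logit_of_linear_predictor(self):
        rm, _ = _driven_rm(seed=3)
        ps = ps_bic(rm, 0)
        assert ps.covariates_used  # drivers found
        import statsmodels.api as sm

        cols = list(ps.covariates_used)
        design = np.column_stack(
            [np.ones(rm.n_reports)] + [rm.drug_column(c) for c in cols]
        )
        refit = sm.Logit(rm.drug_column(0).astype(float), design).fit(disp=0)
        for r in [0, 17, 123, 4567, 9999]:
            eta = refit.params[0] + sum(
                refit.params[1 + k] * rm.X[r, c] for k, c in enumerate(cols)
            )
            assert ps.scores[r] == pytest.approx(expit(eta), abs=1e-6)

    def test_degenerate_exposure_rejected(self):
        X = np.zeros((50, 3), dtype=int)
        X[:, 1] = 1
        X[:10, 2] = 1
        rm = _rm_from_X(X)
        for col in (0, 1):  # all-zero and all-one exposure
            with pytest.raises(ValueError, match="degenerate"):
                ps_bic(rm, col)


class TestPsCisl:
    def test_empty_selection_gives_prevalence(self):
        rm = _independent_rm(n=4000, seed=4)
        ps = ps_cisl(rm, 0, B=10)
        if not ps.covariates_used:
            assert np.allclose(ps.scores, rm.drug_column(0).mean(), atol=1e-9)

    def test_recovers_exposure_drivers(self):
        hits = 0
        for seed in range(5):
            rm, _ = _driven_rm(n=8000, seed=30 + seed)
            ps = ps_cisl(rm, 0, B=25, seed=seed)
            hits += {1, 2, 3} <= set(ps.covariates_used)
        assert hits >= 4


class TestPsHdps:
    def test_balanced_candidate_scores_zero(self):
        """A candidate equally prevalent among exposed and unexposed has
        Bias_M = 1 exactly, whatever its outcome association."""
        n = 400
        x = np.zeros(n, dtype=int)
        x[: n // 2] = 1
        cand = np.tile([1, 0], n // 2)  # exactly half in each exposure arm
        y = (np.arange(n) % 5 == 0).astype(int)
        X = np.column_stack([x, cand])
        rm = _rm_from_X(X, y=y)
        scores = hdps_bias_scores(rm, 0, 0)
        assert scores[1] == pytest.approx(0.0, abs=1e-12)

    def test_null_outcome_association_scores_zero_without_smoothing(self):
        """With RR_CD = 1 the Bross bias is 1 regardless of imbalance; the
        0.1-cell smoothing keeps the score near (not exactly) zero."""
        n = 2000
        rng = np.random.default_rng(6)
        x = (rng.random(n) < 0.3).astype(int)
        cand = np.zeros(n, dtype=int)
        cand[x == 1] = rng.random((x == 1).sum()) < 0.5
        cand[x == 0] = rng.random((x == 0).sum()) < 0.1
        # outcome split independently of the candidate: equal risk both arms
        y = np.zeros(n, dtype=int)
        y[cand == 1] = np.arange((cand == 1).sum()) % 10 == 0
        y[cand == 0] = np.arange((cand == 0).sum()) % 10 == 0
        rm = _rm_from_X(np.column_stack([x, cand]), y=y)
        scores = hdps_bias_scores(rm, 0, 0)
        assert abs(scores[1]) < 0.05

    def test_top_k_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        n, p = 3000, 31
        X = (rng.random((n, p)) < rng.uniform(0.05, 0.3, size=p)).astype(int)
        y = (rng.random(n) < 0.1).astype(int)
        rm = _rm_from_X(X, y=y)
        ps = ps_hdps(rm, 0, 0, n_top=20)

        def bross(c):
            xc = X[:, c]
            x0 = X[:, 0]
            p_c1 = xc[x0 == 1].mean()
            p_c0 = xc[x0 == 0].mean()
            a = (xc & y).sum() + 0.1
            b = (xc & ~y.astype(bool)).sum() + 0.1
            cc = ((1 - xc) & y).sum() + 0.1
            d = ((1 - xc) & ~y.astype(bool)).sum() + 0.1
            rr = (a / (a + b)) / (cc / (cc + d))
            bias = (p_c1 * (rr - 1) + 1) / (p_c0 * (rr - 1) + 1)
            return abs(np.log10(bias))

        oracle_scores = {c: bross(c) for c in range(1, p)}
        expected = set(sorted(oracle_scores, key=lambda c: -oracle_scores[c])[:20])
        assert set(ps.covariates_used) == expected
        assert ps.ae_dependent

    def test_ae_dependence(self):
        """hdPS scores change with the target AE; lasso-based PS does not."""
        rng = np.random.default_rng(8)
        n = 4000
        X = (rng.random((n, 8)) < 0.2).astype(int)
        Y = np.column_stack(
            [
                ((X[:, 1] + (rng.random(n) < 0.05)) > 0).astype(int),
                (rng.random(n) < 0.05).astype(int),
            ]
        )
        rm = ReportMatrix(
            X=sp.csr_matrix(X), Y=sp.csr_matrix(Y),
            drug_ids=[f"D{k}" for k in range(8)], ae_ids=["e1", "e2"],
        )
        h1 = ps_hdps(rm, 0, 0, n_top=3)
        h2 = ps_hdps(rm, 0, 1, n_top=3)
        assert h1.covariates_used != h2.covariates_used or not np.allclose(
            h1.scores, h2.scores
        )
        b1 = ps_bic(rm, 0)
        b2 = ps_bic(rm, 0)  # nothing about the AE enters the estimation
        assert np.array_equal(b1.scores, b2.scores)


class TestPsGtb:
    def test_fixed_seed_is_deterministic(self):
        rm = _independent_rm(n=2000, seed=9)
        a = ps_gtb(rm, 0, n_rounds=20, seed=5)
        b = ps_gtb(rm, 0, n_rounds=20, seed=5)
        assert np.array_equal(a.scores, b.scores)

    def test_pure_noise_predicts_near_prevalence(self):
        """With no exposure signal the boosted model generalizes at chance
        level (out-of-sample AUC ~ 0.5) and calibrates to the prevalence."""
        import xgboost as xgb
        from sklearn.metrics import roc_auc_score

        rm = _independent_rm(n=8000, p=12, seed=10)
        ps = ps_gtb(rm, 0, n_rounds=50, seed=0)
        x = rm.drug_column(0)
        assert abs(ps.scores.mean() - x.mean()) < 0.02
        fresh = _independent_rm(n=8000, p=12, seed=99)
        others = sp.csr_matrix(fresh.X[:, 1:].astype(float))
        preds = ps.booster.predict(xgb.DMatrix(others))
        auc = roc_auc_score(fresh.drug_column(0), preds)
        assert abs(auc - 0.5) < 0.05

    def test_single_perfect_predictor_separates_groups(self):
        rng = np.random.default_rng(11)
        driver = (rng.random(3000) < 0.3).astype(int)
        X = np.column_stack([driver, driver, (rng.random(3000) < 0.2).astype(int)])
        rm = _rm_from_X(X)
        ps = ps_gtb(rm, 0, n_rounds=50, seed=0)
        assert ps.scores[driver == 1].min() > ps.scores[driver == 0].max()


class TestInvariantsAndCache:
    @pytest.mark.parametrize("fn", [ps_bic, ps_gtb])
    def test_calibration_in_the_large(self, fn):
        rm, _ = _driven_rm(n=10000, seed=12)
        ps = fn(rm, 0)
        assert abs(ps.scores.mean() - rm.drug_column(0).mean()) < 0.02

    def test_scores_clamped_and_exposure_excluded(self):
        with pytest.raises(ValueError, match="exposure drug"):
            PropensityScore(0, "BIC", np.array([0.5]), covariates_used=(0,))
        ps = PropensityScore(0, "BIC", np.array([0.0, 1.0, 0.4]), ())
        assert ps.scores.min() == PS_CLAMP
        assert ps.scores.max() == 1 - PS_CLAMP

    def test_cache_roundtrip(self, tmp_path):
        cache = PsCache(directory=str(tmp_path))
        ps = PropensityScore(3, "BIC", np.linspace(0.1, 0.9, 7), (1, 2))
        cache.put(ps)
        fresh = PsCache(directory=str(tmp_path))  # re-read from disk
        hit = fresh.get("BIC", 3)
        assert hit is not None
        assert np.allclose(hit.scores, ps.scores)
        # AE-dependent scores are never cached
        hps = PropensityScore(4, "hdPS", np.array([0.2]), (), ae_dependent=True)
        cache.put(hps)
        assert cache.get("hdPS", 4) is None
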