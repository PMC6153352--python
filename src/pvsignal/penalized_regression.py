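"""L1-penalized logistic engines: lasso paths, BIC selection, CISL.

These are the shared workhorses behind both the multiple-regression signal
detectors and the variable-selection propensity-score estimators.

The penalized objective is the binomial log-likelihood of

    logit(Pr(y = 1)) = beta_0 + X beta

minus ``lambda * ||beta||_1`` (the intercept is never penalized). Fits are
delegated to scikit-learn's L1 logistic solver with ``C = 1 / lambda``; the
path is walked from the data-determined ``lambda_max`` (the smallest penalty
at which the active set is empty) downwards with warm starts.

Model selection strategies on the path:

* **BIC selection** — every distinct active set along the path is refitted as
  an ordinary (unpenalized) logistic model; the set minimizing
  ``BIC = -2 ln L + k ln N`` wins, with ``k`` counting the intercept.
* **CISL** (class-imbalance subsampling lasso) — a stability-selection
  variant for rare outcomes. B subsamples are drawn *with replacement* with
  case reports (y=1) upweighted; a lasso path is fitted on each; for each
  covariate and subsample the statistic ``pi_hat = (1/E) * #{model sizes eta
  at which the coefficient passes the sign constraint}``, where ``E`` is the
  largest active-set size seen across all B paths. A covariate is selected
  when a low quantile (5% or 10%) of its B pi_hat values is positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

#: coefficients below this magnitude are treated as exactly zero when
#: recording active sets (solver slack at the KKT boundary)
ZERO_TOL = 1e-8

DEFAULT_N_LAMBDAS = 50
DEFAULT_LAMBDA_MIN_RATIO = 0.01


def _check_binary_outcome(y: np.ndarray, name: str = "outcome") -> np.ndarray:
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    if classes.size < 2:
        raise ValueError(f"{name} has a single class (all {int(classes[0])}); cannot fit")
    return y.astype(np.float64)


def lambda_max(y, X) -> float:
    """Smallest penalty at which the lasso solution is the null model.

    Equals the sup-norm of the log-likelihood gradient at the intercept-only
    fit: ``max_i |X_i' (y - mean(y))|``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    resid = y - y.mean()
    grad = np.abs(np.asarray(X.T @ resid)).ravel()
    return float(grad.max())


def default_lambda_grid(
    y,
    X,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max to min_ratio * lambda_max."""
    lmax = lambda_max(y, X)
    if lmax <= 0:  # outcome orthogonal to every covariate; any tiny grid works
        lmax = 1.0
    return np.geomspace(lmax, min_ratio * lmax, n_lambdas)


@dataclass
class LassoPath:
    """Solutions of the L1-penalized logistic fit along a decreasing penalty grid."""

    lambdas: np.ndarray  # strictly decreasing
    coefs: np.ndarray  # (n_lambdas, n_covariates), zeros outside active sets
    intercepts: np.ndarray  # (n_lambdas,)

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.ndim != 1 or np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")

    @property
    def n_points(self) -> int:
        return len(self.lambdas)

    def active_set(self, k: int) -> tuple[int, ...]:
        return tuple(np.flatnonzero(np.abs(self.coefs[k]) > ZERO_TOL))

    def active_sets(self) -> list[tuple[int, ...]]:
        return [self.active_set(k) for k in range(self.n_points)]

    def distinct_active_sets(self) -> list[tuple[int, ...]]:
        seen, out = set(), []
        for s in self.active_sets():
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out


def lasso_logistic_path(
    y,
    X,
    lambdas=None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> LassoPath:
    """Fit the L1-penalized logistic path over a decreasing penalty grid.

    Parameters
    ----------
    y : (n,) binary outcome, both classes present.
    X : (n, p) binary covariate matrix (dense or sparse).
    lambdas : optional explicit decreasing grid; defaults to 50 log-spaced
        values from the data-determined lambda_max down to 1% of it.
        ``lambda = 0`` entries are fitted unpenalized.
    """
    y = _check_binary_outcome(y)
    if sp.issparse(X):
        X = sp.csr_matrix(X).astype(np.float64)
        p = X.shape[1]
    else:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        p = X.shape[1]
    if p < 1:
        raise ValueError("X needs at least one covariate column")
    if lambdas is None:
        lambdas = default_lambda_grid(y, X)
    lambdas = np.asarray(lambdas, dtype=float)

    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    clf = LogisticRegression(
        penalty="l1",
        solver="liblinear",
        C=1.0,
        fit_intercept=True,
        # liblinear penalizes the intercept through the bias feature; a large
        # scaling makes that penalty (lambda/scale * |b0|) negligible
        intercept_scaling=1e4,
        tol=tol,
        max_iter=max_iter,
        warm_start=True,
        random_state=0,  # liblinear shuffles internally; pin for bit-reproducibility
    )
    unpen = None
    for k, lam in enumerate(lambdas):
        if lam <= 0:
            if unpen is None:
                unpen = LogisticRegression(
                    penalty=None, solver="lbfgs", tol=tol, max_iter=max_iter
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                unpen.fit(X, y)
            coefs[k] = unpen.coef_[0]
            intercepts[k] = unpen.intercept_[0]
            continue
        clf.C = 1.0 / lam
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        coefs[k] = clf.coef_[0]
        intercepts[k] = clf.intercept_[0]
    coefs[np.abs(coefs) <= ZERO_TOL] = 0.0
    return LassoPath(lambdas=lambdas, coefs=coefs, intercepts=intercepts)


# -----------------------------------------------------------------------------
# BIC model selection
# -----------------------------------------------------------------------------

@dataclass
class BicSelection:
    """Winner of BIC selection along a lasso path, with its unpenalized refit."""

    selected: tuple[int, ...]  # covariate indices of the BIC-minimizing set
    bic: float
    params: np.ndarray  # intercept first, then coefficients of `selected`
    bse: np.ndarray  # matching standard errors
    fitted: np.ndarray  # per-observation fitted probabilities
    llf: float
    candidates: dict = field(default_factory=dict, repr=False)  # set -> BIC

    @property
    def coef(self) -> np.ndarray:
        return self.params[1:]

    @property
    def intercept(self) -> float:
        return float(self.params[0])


def _refit_logistic(y, X, cols: tuple[int, ...]):
    """Unpenalized logistic refit on a column subset; None if it does not converge."""
    n = len(y)
    if cols:
        sub = X[:, list(cols)]
        if sp.issparse(sub):
            sub = np.asarray(sub.todense())
        design = np.column_stack([np.ones(n), sub])
    else:
        design = np.ones((n, 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=50, warn_convergence=False)
    except Exception as exc:  # singular matrix, separation, ...
        logger.warning("refit failed for set %s: %s", cols, exc)
        return None
    if not res.mle_retvals.get("converged", False) or not np.isfinite(res.params).all():
        logger.warning("refit did not converge for set %s; skipped", cols)
        return None
    return res


def bic_select(path: LassoPath, y, X, patience: int = None) -> BicSelection:
    """Refit every distinct active set unpenalized; return the BIC minimizer.

    BIC = -2 ln L + k ln N with k = number of coefficients + 1 (intercept) and
    N the number of observations. The intercept-only model is always a
    candidate, so a valid selection exists even if every refit on a non-empty
    set fails.

    ``patience``: optional early stop. Candidate sets are visited in
    increasing size; after ``patience`` consecutive candidates without a BIC
    improvement the remaining (larger) sets are skipped. BIC's ln(N) penalty
    per parameter makes a later, much larger winner implausible, but the
    exhaustive scan (``patience=None``) remains the reference behaviour.
    """
    y = _check_binary_outcome(y)
    n = len(y)
    candidates = path.distinct_active_sets()
    if () not in candidates:
        candidates.append(())
    candidates.sort(key=len)

    best = None
    stall = 0
    bics: dict[tuple[int, ...], float] = {}
    for cols in candidates:
        if patience is not None and stall >= patience:
            break
        res = _refit_logistic(y, X, cols)
        if res is None:
            stall += 1
            continue
        k = len(cols) + 1
        bic = -2.0 * res.llf + k * np.log(n)
        bics[cols] = bic
        if best is None or bic < best[0]:
            best = (bic, cols, res)
            stall = 0
        else:
            stall += 1
    if best is None:
        raise RuntimeError("no candidate model could be refitted (all fits failed)")
    bic, cols, res = best
    return BicSelection(
        selected=cols,
        bic=float(bic),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        fitted=np.asarray(res.predict()),
        llf=float(res.llf),
        candidates=bics,
    )


# -----------------------------------------------------------------------------
# CISL
# -----------------------------------------------------------------------------

@dataclass
class CislResult:
    """Per-covariate empirical distribution of the pi_hat statistic.

    ``pi_hat[i, b]`` is the fraction of the E possible model sizes at which
    covariate i passes the sign constraint in subsample b's lasso path.
    """

    pi_hat: np.ndarray  # (n_covariates, B), entries in [0, 1]
    E: int
    sign_constraint: str

    def selected(self, q: float) -> tuple[int, ...]:
        """Covariates whose lower empirical q-quantile of pi_hat exceeds zero.

        The type-1 (inverted-CDF) sample quantile is used: with B subsamples
        the q-quantile is the ceil(qB)-th order statistic, so a covariate is
        selected iff fewer than ceil(qB) of its B values are zero. At 5% and
        10% a *smaller* q is the stricter rule: selected(0.05) is a subset of
        selected(0.10).
        """
        if not 0 < q < 1:
            raise ValueError("quantile must be in (0, 1)")
        quant = np.quantile(self.pi_hat, q, axis=1, method="inverted_cdf")
        return tuple(np.flatnonzero(quant > 0))


def _case_weighted_probs(y: np.ndarray, target_case_fraction: float) -> np.ndarray:
    """Per-report sampling probabilities upweighting case reports.

    Cases (y=1) get weight w >= 1 chosen so the expected case fraction among
    draws is ``target_case_fraction``; controls get weight 1. If cases are
    already at least that frequent the draw is uniform (never downweight).
    """
    n1 = int(y.sum())
    n0 = len(y) - n1
    t = target_case_fraction
    w_case = max(1.0, (t / (1.0 - t)) * (n0 / max(n1, 1)))
    w = np.where(y > 0, w_case, 1.0)
    return w / w.sum()


def cisl(
    y,
    X,
    B: int = 100,
    lambdas=None,
    sign_constraint: str = "positive",
    subsample_fraction: float = 0.5,
    target_case_fraction: float = 0.25,
    seed: int = 0,
    max_redraws: int = 20,
) -> CislResult:
    """Class-imbalance subsampling lasso selection statistic.

    Parameters
    ----------
    sign_constraint : "positive" (detection: only harmful, beta > 0, counts)
        or "nonzero" (covariate selection for propensity models).
    subsample_fraction : subsample size as a fraction of N, drawn with
        replacement under case-upweighted probabilities.
    """
    if B < 2:
        raise ValueError("need at least B=2 subsamples")
    if sign_constraint not in ("positive", "nonzero"):
        raise ValueError(f"unknown sign constraint {sign_constraint!r}")
    y = _check_binary_outcome(y)
    X = sp.csr_matrix(X).astype(np.float64) if sp.issparse(X) else np.asarray(X, float)
    n, p = X.shape
    m = max(2, int(round(subsample_fraction * n)))
    probs = _case_weighted_probs(y, target_case_fraction)
    rng = np.random.default_rng(seed)

    if lambdas is None:
        lambdas = default_lambda_grid(y, X)

    # per subsample: for each covariate, the set of model sizes eta at which
    # the sign constraint holds; E is only known after all paths are fitted
    size_hits: list[np.ndarray] = []  # (p,) counts of distinct qualifying sizes
    max_size = 0
    for b in range(B):
        for attempt in range(max_redraws):
            idx = rng.choice(n, size=m, replace=True, p=probs)
            ysub = y[idx]
            if 0 < ysub.sum() < m:
                break
            logger.warning("CISL subsample %d attempt %d single-class; redrawn", b, attempt)
        else:
            raise RuntimeError("could not draw a two-class subsample")
        path = lasso_logistic_path(ysub, X[idx], lambdas=lambdas)
        hits, largest = qualifying_size_counts(path, sign_constraint)
        max_size = max(max_size, largest)
        size_hits.append(hits)

    E = max(max_size, 1)
    pi_hat = np.stack(size_hits, axis=1) / E
    return CislResult(pi_hat=pi_hat, E=E, sign_constraint=sign_constraint)


def qualifying_size_counts(path: LassoPath, sign_constraint: str):
    """Per covariate, the number of distinct model sizes eta at which its
    coefficient passes the sign constraint somewhere on the path; also the
    largest active-set size on the path. The subsample-level building block
    of the pi_hat statistic (before division by E)."""
    p = path.coefs.shape[1]
    hits = [set() for _ in range(p)]
    largest = 0
    for k in range(path.n_points):
        active = np.flatnonzero(np.abs(path.coefs[k]) > ZERO_TOL)
        eta = active.size
        if eta == 0:
            continue
        largest = max(largest, eta)
        if sign_constraint == "positive":
            qual = active[path.coefs[k][active] > ZERO_TOL]
        else:
            qual = active
        for i in qual:
            hits[i].add(eta)
    return np.array([len(s) for s in hits], dtype=float), largest
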