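"""Turning a propensity score into a per-(drug, AE) association test.

Three integration strategies:

* **adjustment** — logistic model of the AE on (exposure, PS), the PS entering
  on the probability scale as an extra covariate;
* **IPTW** — inverse probability of treatment weighting,
  ``w = X/e + (1-X)/(1-e)``, followed by a weighted univariate logistic fit;
* **MW** — matching weights, ``w = min(e, 1-e) * [X/e + (1-X)/(1-e)]``,
  a bounded-weight analogue of pair matching on the PS.

Weighted fits solve the weight-scaled logistic score equations; by default the
standard error is the robust (sandwich) estimator with the weights treated as
fixed, which is the standard choice for IPTW/MW inference. The alternative
is the model-based (inverse-information) variance via ``robust=False``.

All tests are one-sided against the harmful direction (log-OR > 0), the
alternative of interest in pharmacovigilance screening:
``p = 1 - Phi(beta_hat / SE)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .propensity_estimation import PropensityScore

logger = logging.getLogger(__name__)

STRATEGIES = ("adjust", "iptw", "mw", "univariate")


@dataclass
class WeightVector:
    """Per-report balancing weights derived from a propensity score."""

    kind: str  # "IPTW" or "MW"
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.kind not in ("IPTW", "MW"):
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")


@dataclass
class AssociationResult:
    """One (drug, AE) association estimate with a one-sided p-value."""

    drug_index: int
    ae_index: int
    strategy: str
    log_or_estimate: float
    standard_error: float
    z: float
    p_one_sided: float

    @property
    def ok(self) -> bool:
        return np.isfinite(self.p_one_sided)


def _scores(ps) -> np.ndarray:
    return ps.scores if isinstance(ps, PropensityScore) else np.asarray(ps, float)


def iptw_weights(ps, X_i) -> WeightVector:
    """Inverse-probability-of-treatment weights: X/e + (1-X)/(1-e)."""
    e = _scores(ps)
    x = np.asarray(X_i, dtype=float)
    if e.shape != x.shape:
        raise ValueError("propensity scores and exposure vector are misaligned")
    return WeightVector(kind="IPTW", w=x / e + (1.0 - x) / (1.0 - e))


def mw_weights(ps, X_i) -> WeightVector:
    """Matching weights: min(e, 1-e) * [X/e + (1-X)/(1-e)]; always in [0, 1]."""
    e = _scores(ps)
    iptw = iptw_weights(ps, X_i)
    return WeightVector(kind="MW", w=np.minimum(e, 1.0 - e) * iptw.w)


def _failed(drug_index, ae_index, strategy) -> AssociationResult:
    return AssociationResult(
        drug_index, ae_index, strategy, np.nan, np.nan, np.nan, np.nan
    )


def _one_sided(beta: float, se: float) -> tuple[float, float]:
    z = beta / se
    # keep p strictly inside (0, 1) despite floating-point saturation of Phi
    p = float(np.clip(norm.sf(z), 1e-300, 1.0 - 1e-16))
    return z, p


def _fit_glm(y, design, weights=None, robust=True):
    """Binomial GLM fit; returns (params, bse) or None on failure."""
    kwargs = {}
    if weights is not None:
        # var_weights: the weight-scaled score equations with per-observation
        # scores w_i * s_i, so HC0 yields the fixed-weight sandwich
        # A^-1 (sum w^2 s s') A^-1 (freq_weights would instead treat a
        # weight-w row as w replicates and overstate the variance)
        kwargs["var_weights"] = weights
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, design, family=sm.families.Binomial(), **kwargs)
            res = model.fit(cov_type="HC0" if robust else "nonrobust", maxiter=100)
    except Exception as exc:
        logger.warning("GLM fit failed: %s", exc)
        return None
    if not np.isfinite(res.params).all() or not np.isfinite(res.bse).all():
        return None
    if not getattr(res, "converged", True):
        return None
    return res


def weighted_univariate_test(
    Y_j,
    X_i,
    weights: WeightVector = None,
    drug_index: int = 0,
    ae_index: int = 0,
    robust: bool = True,
) -> AssociationResult:
    """Weighted (or unweighted) univariate logistic test of AE on exposure.

    With ``weights=None`` or unit weights this reduces to the plain univariate
    logistic regression used by disproportionality-style screening.
    """
    y = np.asarray(Y_j, dtype=float)
    x = np.asarray(X_i, dtype=float)
    strategy = "univariate" if weights is None else weights.kind.lower()
    w = None if weights is None else weights.w
    if w is not None:
        wsum1 = w[y > 0].sum()
        if wsum1 <= 0 or wsum1 >= w.sum():
            logger.warning("zero weighted outcome cell; test flagged NA")
            return _failed(drug_index, ae_index, strategy)
        # weighted 2x2 cells: exposure x outcome must all carry weight
        cells = [
            w[(x > 0) & (y > 0)].sum(),
            w[(x > 0) & (y == 0)].sum(),
            w[(x == 0) & (y > 0)].sum(),
            w[(x == 0) & (y == 0)].sum(),
        ]
        if min(cells) <= 0:
            logger.warning("zero weighted 2x2 cell; test flagged NA")
            return _failed(drug_index, ae_index, strategy)
    elif y.min() == y.max() or x.min() == x.max():
        return _failed(drug_index, ae_index, strategy)

    design = np.column_stack([np.ones_like(x), x])
    res = _fit_glm(y, design, weights=w, robust=robust and w is not None)
    if res is None:
        return _failed(drug_index, ae_index, strategy)
    beta, se = float(res.params[1]), float(res.bse[1])
    if se <= 0 or not np.isfinite(se):
        return _failed(drug_index, ae_index, strategy)
    z, p = _one_sided(beta, se)
    return AssociationResult(drug_index, ae_index, strategy, beta, se, z, p)


def adjusted_test(
    Y_j,
    X_i,
    ps,
    drug_index: int = 0,
    ae_index: int = 0,
) -> AssociationResult:
    """PS-adjusted logistic test: AE ~ exposure + PS (probability scale)."""
    y = np.asarray(Y_j, dtype=float)
    x = np.asarray(X_i, dtype=float)
    e = _scores(ps)
    if np.ptp(e) < 1e-12:
        logger.warning(
            "constant propensity score (drug %d): PS column collinear with the "
            "intercept, dropped; estimate equals the univariate fit", drug_index
        )
        uni = weighted_univariate_test(
            y, x, None, drug_index=drug_index, ae_index=ae_index
        )
        return AssociationResult(
            drug_index, ae_index, "adjust", uni.log_or_estimate,
            uni.standard_error, uni.z, uni.p_one_sided,
        )
    design = np.column_stack([np.ones_like(x), x, e])
    res = _fit_glm(y, design, robust=False)
    if res is None:
        return _failed(drug_index, ae_index, "adjust")
    beta, se = float(res.params[1]), float(res.bse[1])
    if se <= 0 or not np.isfinite(se):
        return _failed(drug_index, ae_index, "adjust")
    z, p = _one_sided(beta, se)
    return AssociationResult(drug_index, ae_index, "adjust", beta, se, z, p)


def trim_weights(weights: WeightVector, cap: float) -> WeightVector:
    """Cap weights at a fixed value (optional IPTW stabilisation, off by default)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return WeightVector(kind=weights.kind, w=np.minimum(weights.w, cap))
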