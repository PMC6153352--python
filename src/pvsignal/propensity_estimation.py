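"""Per-drug propensity-score estimation in high dimension.

For a target drug, the propensity score (PS) is the probability that a report
lists that drug, conditional on the other drugs on the report. Four
estimators are provided, mirroring the main strategies used for
high-dimensional observational data:

* ``ps_bic``  — covariates picked by BIC selection along a lasso path of the
  exposure on all other drugs, then an unpenalized logistic PS model.
* ``ps_cisl`` — covariates picked by CISL with the *nonzero* sign constraint
  at the 10% quantile, then an unpenalized logistic PS model.
* ``ps_hdps`` — the high-dimensional-PS prioritization: candidates are ranked
  by their multiplicative confounding potential (Bross bias formula) for the
  *specific* adverse event under study, and the top 20 enter the PS model.
  This is the only AE-dependent estimator.
* ``ps_gtb``  — gradient tree boosting of the exposure on all other drugs
  (learning rate 0.1, default booster settings otherwise).

All scores are clamped to [1e-6, 1 - 1e-6] so that downstream inverse
-probability weights stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import xgboost as xgb

from .data_core import ReportMatrix
from .penalized_regression import (
    _refit_logistic,
    bic_select,
    cisl,
    lasso_logistic_path,
)

logger = logging.getLogger(__name__)

PS_CLAMP = 1e-6

PS_METHODS = ("BIC", "CISL", "hdPS", "GTB")


@dataclass
class PropensityScore:
    """Estimated per-report exposure probability for one drug."""

    drug_index: int
    method: str  # one of PS_METHODS
    scores: np.ndarray  # clamped to [PS_CLAMP, 1 - PS_CLAMP]
    covariates_used: tuple[int, ...]  # drug indices in the PS model ((), for GTB)
    ae_dependent: bool = False

    def __post_init__(self):
        if self.method not in PS_METHODS:
            raise ValueError(f"unknown PS method {self.method!r}")
        self.scores = np.clip(np.asarray(self.scores, float), PS_CLAMP, 1 - PS_CLAMP)
        if self.drug_index in self.covariates_used:
            raise ValueError("PS model must not contain the exposure drug itself")


def _exposure_and_others(rm: ReportMatrix, drug_index: int):
    x = rm.drug_column(drug_index).astype(np.float64)
    n1 = x.sum()
    if n1 == 0 or n1 == len(x):
        raise ValueError(
            f"drug {rm.drug_ids[drug_index]!r} is degenerate (all {int(x[0])}); cannot model exposure"
        )
    others = np.array([k for k in range(rm.n_drugs) if k != drug_index])
    Z = rm.X[:, others].astype(np.float64)
    return x, Z, others


def _refit_ps(x, Z, local_cols, others, drug_index, method, ae_dependent=False):
    """Unpenalized logistic PS model on selected columns; constant PS fallback."""
    res = _refit_logistic(x, Z, tuple(local_cols)) if len(local_cols) else None
    if res is None and len(local_cols):
        logger.warning("PS refit failed for drug %d; falling back to intercept-only", drug_index)
    if res is None:
        res = _refit_logistic(x, Z, ())
        local_cols = ()
    scores = np.asarray(res.predict())
    return PropensityScore(
        drug_index=drug_index,
        method=method,
        scores=scores,
        covariates_used=tuple(int(others[c]) for c in local_cols),
        ae_dependent=ae_dependent,
    )


def ps_bic(
    rm: ReportMatrix, drug_index: int, lambdas=None, patience: int = 10
) -> PropensityScore:
    """PS from the BIC-minimizing lasso active set (exposure ~ other drugs)."""
    x, Z, others = _exposure_and_others(rm, drug_index)
    path = lasso_logistic_path(x, Z, lambdas=lambdas)
    sel = bic_select(path, x, Z, patience=patience)
    return PropensityScore(
        drug_index=drug_index,
        method="BIC",
        scores=sel.fitted,
        covariates_used=tuple(int(others[c]) for c in sel.selected),
    )


def ps_cisl(
    rm: ReportMatrix,
    drug_index: int,
    B: int = 100,
    quantile: float = 0.10,
    seed: int = 0,
    **cisl_kwargs,
) -> PropensityScore:
    """PS from the CISL-selected covariates (nonzero sign constraint, 10% quantile)."""
    x, Z, others = _exposure_and_others(rm, drug_index)
    result = cisl(x, Z, B=B, sign_constraint="nonzero", seed=seed, **cisl_kwargs)
    sel = result.selected(quantile)
    if not sel:
        logger.info("CISL selected no covariates for drug %d; constant PS", drug_index)
    return _refit_ps(x, Z, sel, others, drug_index, "CISL")


def hdps_bias_scores(rm: ReportMatrix, drug_index: int, ae_index: int) -> np.ndarray:
    """Multiplicative confounding-potential score of every candidate drug.

    For candidate c with prevalence ``P_C1`` among exposed and ``P_C0`` among
    unexposed reports, and AE risk ratio ``RR_CD`` across candidate-present vs
    candidate-absent reports, the Bross multiplicative bias is

        Bias_M = [P_C1 (RR_CD - 1) + 1] / [P_C0 (RR_CD - 1) + 1]

    and the ranking score is ``|log10 Bias_M|``. RR_CD is computed with 0.1
    added to all four cells of the candidate x AE table to guard zero cells.
    The exposure drug itself scores NaN.
    """
    x = rm.drug_column(drug_index).astype(np.float64)
    y = rm.ae_column(ae_index).astype(np.float64)
    n = rm.n_reports
    n_exposed = x.sum()
    col_sums = np.asarray(rm.X.sum(axis=0, dtype=np.int64), dtype=float).ravel()  # candidate totals
    with_exposed = np.asarray(rm.X.T @ x).ravel()  # candidate & exposed
    with_ae = np.asarray(rm.X.T @ y).ravel()  # candidate & AE (cell a)

    P_C1 = with_exposed / n_exposed
    P_C0 = (col_sums - with_exposed) / (n - n_exposed)

    a = with_ae + 0.1
    b = (col_sums - with_ae) + 0.1
    c = (y.sum() - with_ae) + 0.1
    d = (n - col_sums - (y.sum() - with_ae)) + 0.1
    rr = (a / (a + b)) / (c / (c + d))

    bias = (P_C1 * (rr - 1.0) + 1.0) / (P_C0 * (rr - 1.0) + 1.0)
    score = np.abs(np.log10(bias))
    score[drug_index] = np.nan
    return score


def ps_hdps(
    rm: ReportMatrix, drug_index: int, ae_index: int, n_top: int = 20
) -> PropensityScore:
    """PS from the top-ranked confounding candidates for a specific AE."""
    x, Z, others = _exposure_and_others(rm, drug_index)
    scores = hdps_bias_scores(rm, drug_index, ae_index)[others]
    k = min(n_top, len(others))
    # stable top-k: score descending, candidate index ascending on ties
    order = np.lexsort((others, -scores))
    top = sorted(order[:k])
    return _refit_ps(x, Z, top, others, drug_index, "hdPS", ae_dependent=True)


def ps_gtb(
    rm: ReportMatrix,
    drug_index: int,
    learning_rate: float = 0.1,
    n_rounds: int = 100,
    seed: int = 0,
) -> PropensityScore:
    """PS from gradient tree boosting of the exposure on all other drugs."""
    x, Z, _ = _exposure_and_others(rm, drug_index)
    dtrain = xgb.DMatrix(sp.csr_matrix(Z), label=x)
    params = {
        "objective": "binary:logistic",
        "eta": learning_rate,
        "nthread": 1,
        "seed": int(seed),
    }
    booster = xgb.train(params, dtrain, num_boost_round=n_rounds)
    ps = PropensityScore(
        drug_index=drug_index,
        method="GTB",
        scores=booster.predict(dtrain),
        covariates_used=(),
    )
    ps.booster = booster  # fitted model kept for prediction on new reports
    return ps


# -----------------------------------------------------------------------------
# Optional on-disk PS cache (AE-independent scores are reusable across outcomes)
# -----------------------------------------------------------------------------

@dataclass
class PsCache:
    """In-memory / on-disk cache of AE-independent propensity scores."""

    directory: str = None
    _mem: dict = field(default_factory=dict, repr=False)

    def _path(self, method: str, drug_index: int):
        import os

        return os.path.join(self.directory, f"ps_{method}_{drug_index}.csv")

    def get(self, method: str, drug_index: int):
        key = (method, drug_index)
        if key in self._mem:
            return self._mem[key]
        if self.directory:
            import os

            p = self._path(method, drug_index)
            if os.path.exists(p):
                scores = np.loadtxt(p)
                ps = PropensityScore(drug_index, method, scores, ())
                self._mem[key] = ps
                return ps
        return None

    def put(self, ps: PropensityScore) -> None:
        if ps.ae_dependent:
            return  # AE-dependent scores are not reusable across outcomes
        self._mem[(ps.method, ps.drug_index)] = ps
        if self.directory:
            import os

            os.makedirs(self.directory, exist_ok=True)
            np.savetxt(self._path(ps.method, ps.drug_index), ps.scores)
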