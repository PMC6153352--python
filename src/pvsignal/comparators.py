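"""Signal detectors behind a common interface.

Every detector consumes a :class:`~pvsignal.data_core.ReportMatrix` (already
restricted to eligible drugs) and one AE column, and emits a SignalTable with
one row per drug, so the evaluation harness does not care which method
produced the decisions.

* ``univariate_detector`` — per-drug unadjusted logistic regression (the
  individual-report analogue of a reporting-odds-ratio screen), one-sided
  p-values, BH-FDR decisions.
* ``bic_lasso_detector`` — one lasso path of the AE on all drugs, BIC model
  selection, signals = drugs with a *positive* coefficient in the refit of
  the BIC-minimizing model (a sign rule, not a test). Refit Wald p-values
  (two-sided halved to one-sided) are attached for ranking only.
* ``cisl_detector`` — CISL with the positive sign constraint; signals are the
  covariates selected at the requested quantile. No p-values: the selection
  itself is the decision.
* ``ps_detector`` — any of the four PS estimators combined with adjustment,
  IPTW or MW inference, then BH-FDR decisions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_core import ReportMatrix
from .multiplicity import declare_signals, make_signal_table
from .penalized_regression import bic_select, cisl, lasso_logistic_path
from .propensity_estimation import PsCache, ps_bic, ps_cisl, ps_gtb, ps_hdps
from .ps_inference import (
    adjusted_test,
    iptw_weights,
    mw_weights,
    trim_weights,
    weighted_univariate_test,
)

logger = logging.getLogger(__name__)


def univariate_detector(
    rm: ReportMatrix, ae_index: int, fdr_level: float = 0.05
) -> pd.DataFrame:
    """Unadjusted per-drug logistic screen with FDR decisions."""
    y = rm.ae_column(ae_index)
    estimates, pvals = [], []
    for i in range(rm.n_drugs):
        res = weighted_univariate_test(
            y, rm.drug_column(i), None, drug_index=i, ae_index=ae_index
        )
        estimates.append(res.log_or_estimate)
        pvals.append(res.p_one_sided)
    n_na = int(np.sum(~np.isfinite(pvals)))
    if n_na:
        logger.info("univariate: %d degenerate fits flagged NA", n_na)
    table = make_signal_table(
        rm.drug_ids, rm.ae_ids[ae_index], "univ", "univariate", estimates, pvals
    )
    return declare_signals(table, fdr_level)


def bic_lasso_detector(
    rm: ReportMatrix, ae_index: int, lambdas=None, patience: int = 10
) -> pd.DataFrame:
    """Multiple-regression detector: positive coefficients of the BIC winner."""
    y = rm.ae_column(ae_index)
    path = lasso_logistic_path(y, rm.X.astype(np.float64), lambdas=lambdas)
    sel = bic_select(path, y, rm.X.astype(np.float64), patience=patience)

    estimates = np.full(rm.n_drugs, np.nan)
    pvals = np.full(rm.n_drugs, np.nan)
    signal = np.zeros(rm.n_drugs, dtype=bool)
    for pos, col in enumerate(sel.selected):
        beta = sel.params[pos + 1]
        se = sel.bse[pos + 1]
        estimates[col] = beta
        # two-sided Wald halved to one-sided (harmful direction) for ranking
        pvals[col] = float(norm.sf(beta / se)) if se > 0 else np.nan
        signal[col] = beta > 0
    table = make_signal_table(
        rm.drug_ids, rm.ae_ids[ae_index], "bic-lasso", "multiple", estimates, pvals
    )
    table["signal"] = signal
    return table


def cisl_detector(
    rm: ReportMatrix,
    ae_index: int,
    quantile: float = 0.10,
    B: int = 100,
    seed: int = 0,
    **cisl_kwargs,
) -> pd.DataFrame:
    """Stability-selection detector: CISL with the positive sign constraint."""
    y = rm.ae_column(ae_index)
    result = cisl(
        y, rm.X.astype(np.float64), B=B, sign_constraint="positive",
        seed=seed, **cisl_kwargs,
    )
    selected = set(result.selected(quantile))
    method = f"cisl-{int(round(quantile * 100))}"
    table = make_signal_table(
        rm.drug_ids, rm.ae_ids[ae_index], method, "multiple",
        np.full(rm.n_drugs, np.nan), np.full(rm.n_drugs, np.nan),
    )
    table["signal"] = [i in selected for i in range(rm.n_drugs)]
    return table


PS_ESTIMATORS = ("bic", "cisl", "hdps", "gtb")
PS_STRATEGIES = ("adjust", "iptw", "mw")


def estimate_ps(
    rm: ReportMatrix,
    drug_index: int,
    ps_method: str,
    ae_index: int = None,
    seed: int = 0,
    cache: PsCache = None,
    **kwargs,
):
    """Dispatch to one PS estimator, going through the cache when possible."""
    ps_method = ps_method.lower()
    if ps_method not in PS_ESTIMATORS:
        raise ValueError(f"unknown PS estimator {ps_method!r}")
    if cache is not None and ps_method != "hdps":
        hit = cache.get(ps_method.upper() if ps_method != "hdps" else "hdPS", drug_index)
        if hit is not None:
            return hit
    if ps_method == "bic":
        ps = ps_bic(rm, drug_index, **kwargs)
    elif ps_method == "cisl":
        ps = ps_cisl(rm, drug_index, seed=seed, **kwargs)
    elif ps_method == "hdps":
        if ae_index is None:
            raise ValueError("hdPS needs the target AE column")
        ps = ps_hdps(rm, drug_index, ae_index, **kwargs)
    else:
        ps = ps_gtb(rm, drug_index, seed=seed, **kwargs)
    if cache is not None:
        cache.put(ps)
    return ps


def ps_detector(
    rm: ReportMatrix,
    ae_index: int,
    ps_method: str = "bic",
    strategy: str = "mw",
    fdr_level: float = 0.05,
    seed: int = 0,
    cache: PsCache = None,
    robust: bool = True,
    iptw_cap: float = None,
    ps_kwargs: dict = None,
) -> pd.DataFrame:
    """PS-based detector: estimate a PS per drug, test, adjust for multiplicity."""
    if strategy not in PS_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if ps_method.lower() not in PS_ESTIMATORS:
        raise ValueError(f"unknown PS estimator {ps_method!r}")
    y = rm.ae_column(ae_index)
    estimates = np.full(rm.n_drugs, np.nan)
    pvals = np.full(rm.n_drugs, np.nan)
    for i in range(rm.n_drugs):
        try:
            ps = estimate_ps(
                rm, i, ps_method, ae_index=ae_index, seed=seed, cache=cache,
                **(ps_kwargs or {}),
            )
        except ValueError as exc:
            logger.warning("PS estimation failed for drug %d: %s", i, exc)
            continue
        x = rm.drug_column(i)
        if strategy == "adjust":
            res = adjusted_test(y, x, ps, drug_index=i, ae_index=ae_index)
        else:
            wv = iptw_weights(ps, x) if strategy == "iptw" else mw_weights(ps, x)
            if strategy == "iptw" and iptw_cap is not None:
                wv = trim_weights(wv, iptw_cap)
            res = weighted_univariate_test(
                y, x, wv, drug_index=i, ae_index=ae_index, robust=robust
            )
        estimates[i] = res.log_or_estimate
        pvals[i] = res.p_one_sided
    prefix = {"adjust": "adjustPS", "iptw": "iptwPS", "mw": "mwPS"}[strategy]
    method = f"{prefix}-{ps_method.upper() if ps_method != 'hdps' else 'hdPS'}"
    table = make_signal_table(
        rm.drug_ids, rm.ae_ids[ae_index], method, strategy, estimates, pvals
    )
    return declare_signals(table, fdr_level)
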