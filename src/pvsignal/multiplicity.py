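"""FDR-adjusted p-values and signal decisions.

Each detector produces one one-sided p-value per tested (drug, AE) pair; the
Benjamini-Hochberg step-up procedure converts them into FDR-adjusted
p-values, and a pair is declared a signal when its adjusted p-value falls
below the chosen FDR level (5% by default). Failed fits carry NA p-values;
they are passed through untouched and excluded from the number of tests m.

A :class:`SignalTable` is a pandas DataFrame with columns
``drug, ae, method, strategy, estimate, p, p_fdr, signal``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["drug", "ae", "method", "strategy", "estimate", "p", "p_fdr", "signal"]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NA entries are returned as NA and do not count toward the number of
    tests. The empty input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    n_na = int((~ok).sum())
    if n_na:
        logger.info("fdr_adjust: %d NA p-values passed through (excluded from m)", n_na)
    return out


def make_signal_table(
    drugs,
    ae: str,
    method: str,
    strategy: str,
    estimates,
    p_values,
) -> pd.DataFrame:
    """Assemble a SignalTable skeleton (no decisions yet)."""
    return pd.DataFrame(
        {
            "drug": list(drugs),
            "ae": ae,
            "method": method,
            "strategy": strategy,
            "estimate": np.asarray(estimates, dtype=float),
            "p": np.asarray(p_values, dtype=float),
            "p_fdr": np.nan,
            "signal": False,
        }
    )


def declare_signals(table: pd.DataFrame, fdr_level: float = 0.05) -> pd.DataFrame:
    """Adjust p-values (if not already) and set the is-signal flag.

    A pair is a signal iff its FDR-adjusted p-value is at most ``fdr_level``
    (the step-up rule rejects at equality). Rows with NA p-values never
    become signals.
    """
    if not 0 < fdr_level <= 1:
        raise ValueError("fdr_level must be in (0, 1]")
    out = table.copy()
    if out.empty:
        return out
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    padj = out["p_fdr"].to_numpy()
    out["signal"] = np.isfinite(padj) & (padj <= fdr_level)
    n_na = int(out["p"].isna().sum())
    logger.info(
        "declare_signals: %d/%d signals at FDR %.3g (%d NA fits excluded)",
        int(out["signal"].sum()), len(out), fdr_level, n_na,
    )
    return out


def write_signal_tsv(table: pd.DataFrame, path) -> None:
    """Write a SignalTable as TSV in deterministic (drug, ae, method) order."""
    out = table.loc[:, SIGNAL_COLUMNS].sort_values(
        ["drug", "ae", "method"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False)


def read_signal_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SIGNAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"signal TSV missing columns: {sorted(missing)}")
    return df
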