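"""Scoring signal tables against a reference set of known signals.

A reference set labels some (drug, AE) pairs ``positive`` (established
signals) or ``negative`` (established non-signals); every other pair is
``unknown``. Declared signals with unknown status count toward the number of
signals generated but not toward any error rate:

* PPV          = 100 * TP / (signals with known status)
* FDP          = 100 * FP / (signals with known status)   (PPV + FDP = 100)
* sensitivity  = 100 * TP / (positive pairs in the reference)
* specificity  = 100 * (negatives not flagged) / (negative pairs)

The ranked-detection curve reproduces cumulative true/false positive counts
as signals are consumed in ascending p-value order, and the
observed-vs-expected table joins per-pair co-report counts onto declared
signals for disproportionality-style scatter plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_core import ReportMatrix, pair_counts, read_reference_tsv

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSet:
    """(drug, ae) -> label in {positive, negative, unknown} with counts."""

    pairs: dict

    def __post_init__(self):
        bad = {v for v in self.pairs.values()} - {"positive", "negative", "unknown"}
        if bad:
            raise ValueError(f"invalid reference labels: {sorted(bad)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceSet":
        return cls({(r.drug, r.ae): r.label for r in df.itertuples()})

    @classmethod
    def from_tsv(cls, path) -> "ReferenceSet":
        return cls.from_frame(read_reference_tsv(path))

    @classmethod
    def from_truth(cls, truth: pd.DataFrame, ae: str) -> "ReferenceSet":
        """Reference set from simulated ground truth: true signals are positive
        controls, every other drug is a negative control."""
        return cls(
            {
                (r.drug, ae): ("positive" if r.label == "true_signal" else "negative")
                for r in truth.itertuples()
            }
        )

    def label(self, drug: str, ae: str) -> str:
        return self.pairs.get((drug, ae), "unknown")

    @property
    def n_positive(self) -> int:
        return sum(1 for v in self.pairs.values() if v == "positive")

    @property
    def n_negative(self) -> int:
        return sum(1 for v in self.pairs.values() if v == "negative")


@dataclass
class PerformanceReport:
    """One row of a Table-2-style performance summary (percentages in [0, 100])."""

    n_generated: int
    n_known_status: int
    tp: int
    fp: int
    n_positive: int
    n_negative: int

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / self.n_known_status if self.n_known_status else float("nan")

    @property
    def fdp(self) -> float:
        return 100.0 * self.fp / self.n_known_status if self.n_known_status else float("nan")

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.n_positive

    @property
    def specificity(self) -> float:
        return 100.0 * (self.n_negative - self.fp) / self.n_negative

    def as_row(self) -> dict:
        r2 = lambda v: round(v, 2) if np.isfinite(v) else v
        return {
            "n_generated": self.n_generated,
            "n_known_status": self.n_known_status,
            "tp": self.tp,
            "ppv": r2(self.ppv),
            "sensitivity": r2(self.sensitivity),
            "fp": self.fp,
            "fdp": r2(self.fdp),
            "specificity": r2(self.specificity),
        }


def evaluate(signals: pd.DataFrame, ref: ReferenceSet) -> PerformanceReport:
    """Score the declared signals of one SignalTable against the reference."""
    if ref.n_positive < 1 or ref.n_negative < 1:
        raise ValueError("reference set needs at least one positive and one negative pair")
    declared = signals.loc[signals["signal"].astype(bool)]
    ref_drugs = {d for d, _ in ref.pairs}
    ref_aes = {a for _, a in ref.pairs}
    if not (set(signals["drug"]) & ref_drugs and set(signals["ae"]) & ref_aes):
        raise ValueError("signal table and reference set share no vocabulary")
    labels = [ref.label(r.drug, r.ae) for r in declared.itertuples()]
    tp = sum(1 for lab in labels if lab == "positive")
    fp = sum(1 for lab in labels if lab == "negative")
    return PerformanceReport(
        n_generated=len(declared),
        n_known_status=tp + fp,
        tp=tp,
        fp=fp,
        n_positive=ref.n_positive,
        n_negative=ref.n_negative,
    )


def performance_from_counts(
    tp: int, fp: int, n_generated: int, n_positive: int, n_negative: int
) -> PerformanceReport:
    """Build a report directly from printed counts (metric arithmetic only)."""
    return PerformanceReport(
        n_generated=n_generated,
        n_known_status=tp + fp,
        tp=tp,
        fp=fp,
        n_positive=n_positive,
        n_negative=n_negative,
    )


def ranked_detection_curve(signals: pd.DataFrame, ref: ReferenceSet) -> pd.DataFrame:
    """Cumulative TP/FP counts over declared signals in ascending p order.

    Ties are broken by estimate descending then drug code ascending, so the
    curve is reproducible. Signal tables without p-values (CISL) yield a
    curve over the selection in drug order, with a warning.
    """
    declared = signals.loc[signals["signal"].astype(bool)].copy()
    if declared.empty:
        return pd.DataFrame(columns=["rank", "drug", "ae", "tp_count", "fp_count"])
    score = declared["p_fdr"].where(declared["p_fdr"].notna(), declared["p"])
    if score.isna().all():
        logger.warning("no ranking score available (selection-only detector); "
                       "curve follows drug order")
        declared["_score"] = 0.0
    else:
        declared["_score"] = score
    declared = declared.sort_values(
        ["_score", "estimate", "drug"],
        ascending=[True, False, True],
        kind="mergesort",
        na_position="last",
    )
    tp = np.cumsum([ref.label(r.drug, r.ae) == "positive" for r in declared.itertuples()])
    fp = np.cumsum([ref.label(r.drug, r.ae) == "negative" for r in declared.itertuples()])
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(declared) + 1),
            "drug": declared["drug"].to_numpy(),
            "ae": declared["ae"].to_numpy(),
            "tp_count": tp,
            "fp_count": fp,
        }
    )


def observed_expected_table(signals: pd.DataFrame, rm: ReportMatrix) -> pd.DataFrame:
    """Join observed (n) and expected (e) co-report counts onto declared signals."""
    declared = signals.loc[signals["signal"].astype(bool)]
    rows = []
    for r in declared.itertuples():
        pc = pair_counts(rm, rm.drug_index(r.drug), rm.ae_index(r.ae))
        rows.append(
            {"drug": r.drug, "ae": r.ae, "n": pc.n, "e": pc.e,
             "risk_ratio": pc.n / pc.e if pc.e > 0 else np.nan}
        )
    return pd.DataFrame(rows, columns=["drug", "ae", "n", "e", "risk_ratio"])


def signal_overlap(tables: dict, top_k: int = None) -> dict:
    """Exact overlap of declared (drug, ae) sets across detectors.

    Returns a dict mapping sorted tuples of detector names to the pairs
    declared by exactly that combination (Venn-style partition).
    """
    sets = {}
    for name, tab in tables.items():
        declared = tab.loc[tab["signal"].astype(bool)]
        if top_k is not None and "p" in declared:
            declared = declared.sort_values(
                ["p_fdr", "p", "drug"], kind="mergesort", na_position="last"
            ).head(top_k)
        sets[name] = {(r.drug, r.ae) for r in declared.itertuples()}
    universe = set().union(*sets.values()) if sets else set()
    partition: dict[tuple, set] = {}
    for pair in universe:
        key = tuple(sorted(name for name, s in sets.items() if pair in s))
        partition.setdefault(key, set()).add(pair)
    return partition
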