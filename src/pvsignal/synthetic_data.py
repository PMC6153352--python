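"""Synthetic spontaneous-reporting databases with planted ground truth.

The generator emulates the structural features of a national
pharmacovigilance database that matter for signal detection: extreme sparsity
(each drug present on a small fraction of reports), a rare composite adverse
event, co-prescription correlation between drugs, and a planted confounding
structure in which some drugs have no effect of their own but are
co-prescribed with a truly causal drug.

Exposure model
--------------
Drugs are partitioned into co-prescription blocks. Each block ``b`` carries a
latent per-report Bernoulli factor ``U_b ~ Bernoulli(f)`` (the report belongs
to the block's therapeutic context). A drug in block ``b`` with target
marginal prevalence ``p`` is switched on with probability

    p_high = p * (1 + a * (1 - f) / f)   if U_b = 1
    p_low  = p * (1 - a)                 if U_b = 0

where ``a = within_block_corr`` in [0, 1). The mixture leaves the marginal
prevalence at exactly ``p`` for every ``a``; ``a = 0`` recovers independent
Bernoulli exposure, and larger ``a`` concentrates the drug's use on the
factor's reports, making drugs in the same block co-occur. Drugs outside any
block are independent Bernoulli(p).

Outcome model
-------------
One composite AE column, drawn per report from a logistic model: the log-odds
of the event is ``baseline_ae_logit + sum_i beta_i X_i``, where ``beta_i`` is
nonzero (log odds-ratio drawn uniformly from ``true_log_or_range``) exactly on
the ``true_signal`` drugs. ``confounded_null`` drugs share a block with a true
signal but have ``beta = 0``: their univariate association with the outcome is
spurious, which is precisely what multivariate and propensity-score detectors
are supposed to resolve.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .data_core import ReportMatrix, write_long_csv, write_sparse_dir

TRUE_SIGNAL = "true_signal"
CONFOUNDED_NULL = "confounded_null"
INDEPENDENT_NULL = "independent_null"

COMPOSITE_AE = "AE_COMPOSITE"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic spontaneous-reporting generator.

    Defaults are sized for desk-scale experiments: 20,000 reports, 200 drugs,
    10 truly associated drugs each paired with a confounded null in its
    co-prescription block, a ~5% composite-event background rate, and drug
    prevalences of 1-5% so every drug has a few hundred reports.
    """

    N: int = 20_000
    I: int = 200
    n_blocks: int = 10
    within_block_corr: float = 0.9
    block_factor_prob: float = 0.1
    drug_prevalence_range: tuple[float, float] = (0.01, 0.05)
    n_true_signals: int = 10
    true_log_or_range: tuple[float, float] = (0.7, 1.5)
    n_confounded_nulls: int = 10
    baseline_ae_logit: float = float(np.log(0.05 / 0.95))
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.drug_prevalence_range
        if not (0 < lo <= hi < 1):
            raise ValueError("drug prevalences must lie in (0, 1)")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must be in [0, 1)")
        if not (0 < self.block_factor_prob < 1):
            raise ValueError("block_factor_prob must be in (0, 1)")
        if self.n_true_signals + self.n_confounded_nulls > self.I:
            raise ValueError("more signal + confounded drugs than drugs")
        if self.N < 1 or self.I < 1 or self.n_blocks < 0:
            raise ValueError("N, I must be positive; n_blocks non-negative")
        if self.n_blocks > self.I:
            raise ValueError("more co-prescription blocks than drugs")
        if self.n_confounded_nulls > 0 and self.n_blocks > self.n_true_signals:
            raise ValueError(
                "confounded nulls need a true signal in their block: "
                "n_blocks must not exceed n_true_signals"
            )
        # p_high must stay a probability at the configured factor prevalence
        f, a = self.block_factor_prob, self.within_block_corr
        if hi * (1 + a * (1 - f) / f) >= 1:
            raise ValueError("within-block high prevalence exceeds 1; lower "
                             "prevalence, correlation, or raise block_factor_prob")


@dataclass
class SimulatedDatabase:
    """A simulated ReportMatrix plus the planted truth used to score detectors."""

    rm: ReportMatrix
    truth: pd.DataFrame  # columns: drug, label, log_or, block
    true_coefficients: np.ndarray = field(repr=False)
    config: SimulationConfig = None

    def drugs_with_label(self, label: str) -> list[str]:
        return self.truth.loc[self.truth["label"] == label, "drug"].tolist()


def _drug_names(I: int) -> list[str]:
    width = len(str(I - 1))
    return [f"D{k:0{width}d}" for k in range(I)]


def simulate(config: SimulationConfig) -> SimulatedDatabase:
    """Draw one synthetic database; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    N, I = config.N, config.I

    labels = np.array(
        [TRUE_SIGNAL] * config.n_true_signals
        + [CONFOUNDED_NULL] * config.n_confounded_nulls
        + [INDEPENDENT_NULL] * (I - config.n_true_signals - config.n_confounded_nulls)
    )
    # block membership: true signal k and confounded null k share block k mod n_blocks
    block = np.full(I, -1, dtype=int)
    if config.n_blocks > 0:
        for k in range(config.n_true_signals):
            block[k] = k % config.n_blocks
        for k in range(config.n_confounded_nulls):
            block[config.n_true_signals + k] = k % config.n_blocks

    lo, hi = config.drug_prevalence_range
    prevalence = rng.uniform(lo, hi, size=I)

    beta = np.zeros(I)
    b_lo, b_hi = config.true_log_or_range
    beta[: config.n_true_signals] = rng.uniform(b_lo, b_hi, size=config.n_true_signals)

    # latent block factors, one Bernoulli per (report, block)
    f, a = config.block_factor_prob, config.within_block_corr
    factors = rng.random((N, max(config.n_blocks, 1))) < f

    X = np.empty((N, I), dtype=np.int8)
    for i in range(I):
        p = prevalence[i]
        if block[i] >= 0:
            p_high = p * (1 + a * (1 - f) / f)
            p_low = p * (1 - a)
            probs = np.where(factors[:, block[i]], p_high, p_low)
        else:
            probs = p
        X[:, i] = rng.random(N) < probs

    logit = config.baseline_ae_logit + X @ beta
    y = (rng.random(N) < expit(logit)).astype(np.int8)

    rm = ReportMatrix(
        X=sp.csr_matrix(X),
        Y=sp.csr_matrix(y[:, None]),
        drug_ids=_drug_names(I),
        ae_ids=[COMPOSITE_AE],
    )
    truth = pd.DataFrame(
        {"drug": rm.drug_ids, "label": labels, "log_or": beta, "block": block}
    )
    return SimulatedDatabase(rm=rm, truth=truth, true_coefficients=beta, config=config)


def write_truth_tsv(db: SimulatedDatabase, path) -> None:
    db.truth.loc[:, ["drug", "label", "log_or"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_database(db: SimulatedDatabase, directory, fmt: str = "sparse") -> None:
    """Persist a simulated database (sparse MTX dir or long CSV) plus truth.tsv."""
    os.makedirs(str(directory), exist_ok=True)
    if fmt == "sparse":
        write_sparse_dir(db.rm, directory)
    elif fmt == "csv":
        write_long_csv(db.rm, os.path.join(str(directory), "reports.csv"))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    write_truth_tsv(db, os.path.join(str(directory), "truth.tsv"))
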