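"""Report-level data model for spontaneous-reporting databases.

Spontaneous-report data are individual case reports: each report lists the
drugs taken (suspected or co-reported) and the adverse events (AEs) observed.
In memory this is a pair of sparse binary indicator matrices over a shared set
of N reports: ``X`` (N x I drugs) and ``Y`` (N x J adverse events), with the
drug and AE vocabularies kept alongside.

Interchange formats
-------------------
* Long CSV: header ``report_id,code,kind`` with ``kind`` in {drug, ae}, one
  triple per line (canonical small-scale format).
* Sparse: MatrixMarket coordinate files for X and Y plus ``drugs.txt`` /
  ``aes.txt`` / ``reports.txt`` label files, one code per line in column
  (resp. row) order.
* Reference signal sets: TSV ``drug<TAB>ae<TAB>label`` with label in
  {positive, negative, unknown}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

DRUG_KIND = "drug"
AE_KIND = "ae"
VALID_KINDS = (DRUG_KIND, AE_KIND)


def _as_binary_csr(m) -> sp.csr_matrix:
    """Coerce to CSR with entries in {0, 1}."""
    m = sp.csr_matrix(m)
    m.eliminate_zeros()
    data = np.asarray(m.data)
    if data.size and not np.isin(data, (0, 1)).all():
        raise ValueError("matrix entries must all be 0 or 1")
    m = m.astype(np.int8)
    m.sum_duplicates()
    return m


@dataclass
class ReportMatrix:
    """Sparse binary report-by-drug and report-by-AE indicator matrices.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix
        N reports x I drugs exposure indicators.
    Y : scipy.sparse.csr_matrix
        N reports x J adverse-event indicators.
    drug_ids, ae_ids : list of str
        Column vocabularies, no duplicates, lengths matching X / Y.
    report_ids : list
        Row identifiers (optional provenance; defaults to 0..N-1).
    """

    X: sp.csr_matrix
    Y: sp.csr_matrix
    drug_ids: list[str]
    ae_ids: list[str]
    report_ids: list = field(default=None)

    def __post_init__(self):
        self.X = _as_binary_csr(self.X)
        self.Y = _as_binary_csr(self.Y)
        self.drug_ids = list(self.drug_ids)
        self.ae_ids = list(self.ae_ids)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X and Y must share the report axis: {self.X.shape[0]} != {self.Y.shape[0]}"
            )
        n, i = self.X.shape
        j = self.Y.shape[1]
        if n < 1 or i < 1 or j < 1:
            raise ValueError("need at least one report, one drug and one AE")
        if len(self.drug_ids) != i:
            raise ValueError("drug_ids length does not match X columns")
        if len(self.ae_ids) != j:
            raise ValueError("ae_ids length does not match Y columns")
        if len(set(self.drug_ids)) != i:
            raise ValueError("duplicate drug codes")
        if len(set(self.ae_ids)) != j:
            raise ValueError("duplicate AE codes")
        if self.report_ids is None:
            self.report_ids = list(range(n))
        elif len(self.report_ids) != n:
            raise ValueError("report_ids length does not match row count")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_reports(self) -> int:
        return self.X.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.X.shape[1]

    @property
    def n_aes(self) -> int:
        return self.Y.shape[1]

    def drug_column(self, drug_index: int) -> np.ndarray:
        return np.asarray(self.X[:, drug_index].todense()).ravel().astype(np.int8)

    def ae_column(self, ae_index: int) -> np.ndarray:
        return np.asarray(self.Y[:, ae_index].todense()).ravel().astype(np.int8)

    def drug_index(self, code: str) -> int:
        return self.drug_ids.index(code)

    def ae_index(self, code: str) -> int:
        return self.ae_ids.index(code)


@dataclass(frozen=True)
class PairCounts:
    """Observed / expected co-report counts for one (drug, AE) pair.

    ``e = N_i * N_j / N`` is the count expected if the drug and the AE were
    reported independently.
    """

    n: int
    N_i: int
    N_j: int
    N: int

    @property
    def e(self) -> float:
        return self.N_i * self.N_j / self.N

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("empty database: N must be positive")
        if not (0 <= self.n <= min(self.N_i, self.N_j) <= self.N):
            raise ValueError(
                f"inconsistent counts n={self.n}, N_i={self.N_i}, N_j={self.N_j}, N={self.N}"
            )


# -----------------------------------------------------------------------------
# Construction from long-format triples
# -----------------------------------------------------------------------------

def build_report_matrix(records) -> ReportMatrix:
    """Build a :class:`ReportMatrix` from (report_id, code, kind) triples.

    Parameters
    ----------
    records : pandas.DataFrame or iterable of 3-tuples
        Columns/fields ``report_id``, ``code``, ``kind`` with kind in
        {"drug", "ae"}. Duplicate triples are deduplicated (indicator data).

    Rows are ordered by sorted report_id, columns by sorted code.
    """
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, ["report_id", "code", "kind"]].copy()
    else:
        df = pd.DataFrame(list(records), columns=["report_id", "code", "kind"])
    if df.empty:
        raise ValueError("no records supplied")
    df["code"] = df["code"].astype(str)
    if (df["code"].str.len() == 0).any():
        raise ValueError("empty code string in records")
    bad = ~df["kind"].isin(VALID_KINDS)
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"record {row} has unknown kind {df.loc[row, 'kind']!r}; expected one of {VALID_KINDS}"
        )
    df = df.drop_duplicates()

    report_ids = sorted(df["report_id"].unique())
    row_of = {r: k for k, r in enumerate(report_ids)}

    def indicator(kind: str):
        sub = df[df["kind"] == kind]
        codes = sorted(sub["code"].unique())
        if not codes:
            raise ValueError(f"no records of kind {kind!r}; need at least one")
        col_of = {c: k for k, c in enumerate(codes)}
        rows = sub["report_id"].map(row_of).to_numpy()
        cols = sub["code"].map(col_of).to_numpy()
        m = sp.coo_matrix(
            (np.ones(len(sub), dtype=np.int8), (rows, cols)),
            shape=(len(report_ids), len(codes)),
        )
        return m.tocsr(), codes

    X, drug_ids = indicator(DRUG_KIND)
    Y, ae_ids = indicator(AE_KIND)
    return ReportMatrix(X=X, Y=Y, drug_ids=drug_ids, ae_ids=ae_ids, report_ids=report_ids)


# -----------------------------------------------------------------------------
# Counting and eligibility filters
# -----------------------------------------------------------------------------

def pair_counts(rm: ReportMatrix, drug_index: int, ae_index: int) -> PairCounts:
    """Exact co-report and marginal counts for one (drug, AE) pair."""
    x = rm.drug_column(drug_index).astype(np.int64)
    y = rm.ae_column(ae_index).astype(np.int64)
    return PairCounts(
        n=int(x @ y),
        N_i=int(x.sum()),
        N_j=int(y.sum()),
        N=rm.n_reports,
    )


class NoEligibleDrugsError(ValueError):
    """Raised when an eligibility filter removes every drug column."""


def filter_eligible_drugs(
    rm: ReportMatrix,
    ae_index: int,
    min_coreports: int = 3,
    min_total: int = 10,
) -> ReportMatrix:
    """Restrict to drugs with enough support for regression modelling.

    A drug is retained iff it has *strictly more than* ``min_coreports``
    reports in common with the target AE and *strictly more than* ``min_total``
    reports overall. Column order is preserved.
    """
    if min_coreports < 0 or min_total < 0:
        raise ValueError("thresholds must be non-negative")
    y = rm.ae_column(ae_index).astype(np.int64)
    co = np.asarray(rm.X.astype(np.int64).T @ y).ravel()
    totals = np.asarray(rm.X.sum(axis=0, dtype=np.int64)).ravel()
    keep = (co > min_coreports) & (totals > min_total)
    if not keep.any():
        raise NoEligibleDrugsError(
            f"no drug has >{min_coreports} co-reports with the AE and >{min_total} reports"
        )
    idx = np.flatnonzero(keep)
    return replace(
        rm,
        X=rm.X[:, idx],
        drug_ids=[rm.drug_ids[k] for k in idx],
    )


def collapse_ae_group(rm: ReportMatrix, ae_codes, group_code: str = "AE_GROUP") -> ReportMatrix:
    """Collapse a set of AE columns into one composite outcome column (logical OR).

    A report contributes once to the composite, however many member codes it
    lists. Used to treat a family of related event codes (e.g. all liver-injury
    preferred terms) as a single outcome.
    """
    idx = [rm.ae_index(c) if isinstance(c, str) else int(c) for c in ae_codes]
    if not idx:
        raise ValueError("empty AE group")
    y = (np.asarray(rm.Y[:, idx].sum(axis=1)).ravel() > 0).astype(np.int8)
    return replace(rm, Y=sp.csr_matrix(y[:, None]), ae_ids=[group_code])


# -----------------------------------------------------------------------------
# Serialization
# -----------------------------------------------------------------------------

def read_long_csv(path) -> ReportMatrix:
    """Read the long-format triple CSV (header: report_id,code,kind)."""
    df = pd.read_csv(path, dtype={"report_id": str, "code": str, "kind": str})
    missing = {"report_id", "code", "kind"} - set(df.columns)
    if missing:
        raise ValueError(f"long CSV missing columns: {sorted(missing)}")
    return build_report_matrix(df)


def write_long_csv(rm: ReportMatrix, path) -> None:
    """Write a ReportMatrix as long-format triples (inverse of read_long_csv)."""
    frames = []
    for mat, codes, kind in ((rm.X, rm.drug_ids, DRUG_KIND), (rm.Y, rm.ae_ids, AE_KIND)):
        coo = mat.tocoo()
        frames.append(
            pd.DataFrame(
                {
                    "report_id": [rm.report_ids[r] for r in coo.row],
                    "code": [codes[c] for c in coo.col],
                    "kind": kind,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["report_id", "kind", "code"], kind="mergesort")
    out.to_csv(path, index=False)


def _read_labels(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_sparse_dir(directory) -> ReportMatrix:
    """Read MatrixMarket X.mtx / Y.mtx plus drugs.txt / aes.txt / reports.txt."""
    d = str(directory)
    X = scipy.io.mmread(os.path.join(d, "X.mtx"))
    Y = scipy.io.mmread(os.path.join(d, "Y.mtx"))
    return ReportMatrix(
        X=X,
        Y=Y,
        drug_ids=_read_labels(os.path.join(d, "drugs.txt")),
        ae_ids=_read_labels(os.path.join(d, "aes.txt")),
        report_ids=_read_labels(os.path.join(d, "reports.txt")),
    )


def write_sparse_dir(rm: ReportMatrix, directory) -> None:
    d = str(directory)
    os.makedirs(d, exist_ok=True)
    scipy.io.mmwrite(os.path.join(d, "X.mtx"), rm.X.tocoo())
    scipy.io.mmwrite(os.path.join(d, "Y.mtx"), rm.Y.tocoo())
    for name, labels in (
        ("drugs.txt", rm.drug_ids),
        ("aes.txt", rm.ae_ids),
        ("reports.txt", rm.report_ids),
    ):
        with open(os.path.join(d, name), "w", encoding="utf-8") as fh:
            fh.writelines(f"{lab}\n" for lab in labels)


REFERENCE_LABELS = ("positive", "negative", "unknown")


def read_reference_tsv(path) -> pd.DataFrame:
    """Read a reference signal set: drug<TAB>ae<TAB>label."""
    df = pd.read_csv(path, sep="\t", names=["drug", "ae", "label"], header=None, dtype=str)
    if df.iloc[0].tolist() == ["drug", "ae", "label"]:  # tolerate an optional header
        df = df.iloc[1:].reset_index(drop=True)
    bad = ~df["label"].isin(REFERENCE_LABELS)
    if bad.any():
        raise ValueError(f"invalid reference labels: {sorted(df.loc[bad, 'label'].unique())}")
    return df
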