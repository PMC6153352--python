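"""End-to-end orchestration: simulate/load -> filter -> detect -> evaluate.

Method names follow the PS-literature nomenclature: ``univ``, ``bic-lasso``,
``cisl-5``, ``cisl-10`` for the non-PS detectors, and ``<strategy>PS-<est>``
(e.g. ``mwPS-BIC``, ``adjustPS-hdPS``, ``iptwPS-GTB``) for the twelve PS
combinations. AE-independent propensity scores (BIC / CISL / GTB) are
estimated once per drug and shared across the adjust / iptw / mw strategies
through a cache.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .comparators import (
    bic_lasso_detector,
    cisl_detector,
    ps_detector,
    univariate_detector,
)
from .data_core import (
    ReportMatrix,
    collapse_ae_group,
    filter_eligible_drugs,
    read_long_csv,
    read_sparse_dir,
)
from .evaluation import ReferenceSet, evaluate
from .multiplicity import write_signal_tsv
from .propensity_estimation import PsCache
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger(__name__)

NON_PS_METHODS = ("univ", "bic-lasso", "cisl-5", "cisl-10")

_PS_PREFIX = {"adjustps": "adjust", "iptwps": "iptw", "mwps": "mw"}
_PS_EST = {"bic": "bic", "cisl": "cisl", "hdps": "hdps", "gtb": "gtb"}


def parse_method(name: str):
    """Map a method name to (kind, details); raises on unknown names."""
    low = name.lower()
    if low in NON_PS_METHODS:
        return ("comparator", low)
    if "-" in low:
        prefix, est = low.split("-", 1)
        if prefix in _PS_PREFIX and est in _PS_EST:
            return ("ps", (_PS_PREFIX[prefix], _PS_EST[est]))
    raise ValueError(
        f"unknown method {name!r}; expected one of {NON_PS_METHODS} or "
        "adjustPS-/iptwPS-/mwPS- followed by BIC, CISL, hdPS or GTB"
    )


def all_method_names() -> list[str]:
    names = list(NON_PS_METHODS)
    for strat in ("adjustPS", "mwPS", "iptwPS"):
        for est in ("BIC", "CISL", "hdPS", "GTB"):
            names.append(f"{strat}-{est}")
    return names


@dataclass
class RunConfig:
    """Configuration of one full comparison run."""

    methods: list = field(default_factory=lambda: ["univ", "bic-lasso", "mwPS-BIC"])
    fdr_level: float = 0.05
    min_coreports: int = 3
    min_total: int = 10
    seed: int = 0
    ae: str = None  # AE code, or None for the first/composite column
    ae_group: list = None  # optional list of AE codes to OR-collapse
    input_csv: str = None  # long-format CSV path ...
    input_sparse: str = None  # ... or sparse MTX directory
    simulation: dict = None  # ... or SimulationConfig fields
    reference_tsv: str = None  # optional external reference set
    output_dir: str = "pvsignal_out"
    robust_variance: bool = True
    iptw_cap: float = None
    detector_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.fdr_level <= 1:
            raise ValueError("fdr_level must be in (0, 1]")
        for m in self.methods:
            parse_method(m)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_inputs(config: RunConfig):
    """Resolve the report matrix and (optional) reference set for a run."""
    truth = None
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
        db = simulate(sim_cfg)
        rm, truth = db.rm, db.truth
    elif config.input_csv:
        rm = read_long_csv(config.input_csv)
    elif config.input_sparse:
        rm = read_sparse_dir(config.input_sparse)
    else:
        raise ValueError("config must provide simulation, input_csv or input_sparse")

    if config.ae_group:
        rm = collapse_ae_group(rm, config.ae_group)
    ae_index = rm.ae_index(config.ae) if config.ae else 0

    ref = None
    if config.reference_tsv:
        ref = ReferenceSet.from_tsv(config.reference_tsv)
    elif truth is not None:
        ref = ReferenceSet.from_truth(truth, rm.ae_ids[ae_index])
    return rm, ae_index, ref, truth


def run_detector(
    rm: ReportMatrix,
    ae_index: int,
    method: str,
    fdr_level: float = 0.05,
    seed: int = 0,
    cache: PsCache = None,
    robust: bool = True,
    iptw_cap: float = None,
    **kwargs,
) -> pd.DataFrame:
    """Run one named detector on an (already filtered) report matrix."""
    kind, details = parse_method(method)
    if kind == "comparator":
        if details == "univ":
            return univariate_detector(rm, ae_index, fdr_level=fdr_level)
        if details == "bic-lasso":
            return bic_lasso_detector(rm, ae_index, **kwargs)
        quantile = 0.05 if details == "cisl-5" else 0.10
        return cisl_detector(rm, ae_index, quantile=quantile, seed=seed, **kwargs)
    strategy, est = details
    return ps_detector(
        rm, ae_index, ps_method=est, strategy=strategy, fdr_level=fdr_level,
        seed=seed, cache=cache, robust=robust, iptw_cap=iptw_cap,
        ps_kwargs=kwargs or None,
    )


def run(config: RunConfig) -> dict:
    """Full pipeline; returns {"signals": {method: table}, "report": DataFrame}."""
    rm, ae_index, ref, truth = _load_inputs(config)
    rm = filter_eligible_drugs(
        rm, ae_index, min_coreports=config.min_coreports, min_total=config.min_total
    )
    logger.info("eligible drugs: %d; reports: %d", rm.n_drugs, rm.n_reports)

    os.makedirs(config.output_dir, exist_ok=True)
    cache = PsCache()  # share AE-independent PS vectors across strategies
    signals: dict[str, pd.DataFrame] = {}
    rows = []
    for method in config.methods:
        table = run_detector(
            rm, ae_index, method, fdr_level=config.fdr_level, seed=config.seed,
            cache=cache, robust=config.robust_variance, iptw_cap=config.iptw_cap,
            **config.detector_kwargs.get(method, {}),
        )
        signals[method] = table
        write_signal_tsv(table, os.path.join(config.output_dir, f"signals_{method}.tsv"))
        logger.info("%s: %d signals", method, int(table["signal"].sum()))
        if ref is not None:
            rows.append({"method": method, **evaluate(table, ref).as_row()})

    report = pd.DataFrame(rows) if rows else None
    if report is not None:
        report.to_csv(
            os.path.join(config.output_dir, "performance.tsv"), sep="\t", index=False
        )
    manifest = {
        "pvsignal_version": __version__,
        "seed": config.seed,
        "fdr_level": config.fdr_level,
        "methods": list(config.methods),
        "min_coreports": config.min_coreports,
        "min_total": config.min_total,
        "n_reports": rm.n_reports,
        "n_eligible_drugs": rm.n_drugs,
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"signals": signals, "report": report, "rm": rm, "truth": truth}
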