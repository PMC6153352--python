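# pvsignal

Signal detection for spontaneous-report pharmacovigilance databases:
propensity-score-based detectors compared against univariate
disproportionality-style screening and penalized multiple logistic
regression, on individual case reports.

## The problem

A pharmacovigilance database is a pile of individual reports, each listing
the drugs a patient took and the adverse events (AEs) observed. Screening
it means testing every (drug, AE) pair for an unexpected association. The
classical univariate screens (reporting odds ratios and friends) ignore the
*other* drugs on each report, so co-prescription confounding and masking
produce false signals. Multiple logistic regression of the event on all
drug indicators fixes that, but in high dimension it needs an L1 penalty,
and the penalty level / decision rule is awkward to calibrate. The strategy
implemented here keeps the multivariate adjustment but moves it into a
propensity score: for each drug, estimate

    ê_i = Pr(X_i = 1 | all other drugs on the report)

with a high-dimensional method (BIC-selected lasso, CISL stability
selection, hdPS confounder ranking, or gradient tree boosting), then test
each (drug, AE) pair with the PS as an adjustment covariate, with inverse
-probability-of-treatment weights `X/ê + (1−X)/(1−ê)`, or with matching
weights `min(ê, 1−ê)·[X/ê + (1−X)/(1−ê)]` — and control the false
discovery rate across all pairs with Benjamini–Hochberg on one-sided Wald
p-values.

Sixteen detectors are available behind one interface: `univ`, `bic-lasso`,
`cisl-5`, `cisl-10`, and `{adjustPS, iptwPS, mwPS} × {BIC, CISL, hdPS, GTB}`.
A synthetic spontaneous-reporting generator with planted ground truth
(true signals, co-prescription blocks, confounded nulls) makes the whole
comparison reproducible without access to any real database, and an
evaluation harness scores any detector against a reference signal set
(PPV, sensitivity, specificity, FDP, ranked-detection curves,
observed-vs-expected counts).

## Worked example

```python
from pvsignal import (SimulationConfig, simulate, filter_eligible_drugs,
                      univariate_detector, ps_detector, ReferenceSet, evaluate)

cfg = SimulationConfig(N=20000, I=40, n_blocks=10,
                       n_true_signals=10, n_confounded_nulls=10, seed=0)
db = simulate(cfg)
rm = filter_eligible_drugs(db.rm, ae_index=0)   # >3 co-reports, >10 reports
ref = ReferenceSet.from_truth(db.truth, rm.ae_ids[0])

for name, tab in {
    "univ":     univariate_detector(rm, 0),
    "mwPS-BIC": ps_detector(rm, 0, ps_method="bic", strategy="mw"),
}.items():
    r = evaluate(tab, ref)
    print(f"{name:9s} signals={r.n_generated:3d} sens={r.sensitivity:5.1f} "
          f"spec={r.specificity:5.1f}")
```

prints

```
univ      signals= 16 sens=100.0 spec= 80.0
mwPS-BIC  signals= 10 sens=100.0 spec=100.0
```

Both detectors find all 10 planted signals, but the univariate screen also
flags 6 of the confounded co-prescription nulls (specificity 80% over the
30 negative-control drugs), while the matching-weight PS detector flags
none — the qualitative ordering this package exists to demonstrate.

There is also a CLI (`pvsignal simulate / detect / evaluate / run-all`)
driven by YAML configs, e.g.

```bash
pvsignal simulate --config sim.yaml --out db/ --seed 42
pvsignal run-all --config run.yaml --seed 42 --fdr 0.05
```

which writes one signal TSV per method, a combined performance table and a
run manifest.

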