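# Methods

`pvsignal` implements and compares signal-detection strategies for
spontaneous-report pharmacovigilance data: a univariate
disproportionality-style screen, two penalized multiple-regression detectors
(BIC-lasso and CISL), and a family of propensity-score (PS) detectors (four
PS estimators crossed with three ways of using the PS), all sharing a
Benjamini–Hochberg FDR decision layer where a hypothesis test exists.

## Data model

A database is a pair of sparse binary indicator matrices over N reports:
`X` (N × I drugs) and `Y` (N × J adverse events). All modelling is
report-level: for a target adverse event `Y_j`, the individual-report
logistic model is

    logit Pr(Y_j = 1) = β_0j + Σ_i β_ij X_i .

Before any detector runs, drugs are filtered for minimal support: a drug is
eligible iff it has **strictly more than** 3 reports in common with the
target event and **strictly more than** 10 reports in total (both
thresholds config-exposed). A family of related event codes can be
OR-collapsed into one composite outcome column; a report counts once however
many member codes it lists.

## Detectors

**Univariate (`univ`).** Per drug, the unadjusted logistic fit of the event
on that drug alone — equivalent to a reporting-odds-ratio screen. One-sided
Wald p-values (harmful direction, β > 0), BH-adjusted, signals at FDR ≤ 5%.

**BIC-lasso.** One L1-penalized logistic path of the event on all eligible
drugs; every distinct active set along the path is refitted *unpenalized*
and scored by `BIC = −2 ln L + k ln N` (k counts the intercept); the signals
are the drugs with a **positive** coefficient in the BIC-minimizing refit.
This is a sign rule, not a test; the refit's one-sided Wald p-values are
attached for ranking only.

**CISL.** A class-imbalance stability-selection variant for rare outcomes.
B subsamples of size N/2 are drawn **with replacement**, with case reports
(y = 1) upweighted so the expected case fraction among draws is 0.25 (cases
are never downweighted if already frequent). A lasso path is fitted per
subsample. With E the largest active-set size seen across all B paths, the
per-covariate, per-subsample statistic is

    π̂_i^b = (1/E) · #{ model sizes η at which β̂_i > 0 somewhere on path b } ,

with "> 0" replaced by "≠ 0" when CISL is used for PS covariate selection.
A covariate is selected when the lower (type-1 / inverted-CDF) empirical
q-quantile of its B values is positive — i.e. fewer than ⌈qB⌉ of the B
values are zero. Because the quantile function is non-decreasing in q, the
5% rule is *stricter* than the 10% rule: `selected(0.05) ⊆ selected(0.10)`,
matching the observed ordering in which the 5% variant generates fewer
signals. Selection itself is the decision; no p-values exist.

**PS detectors.** For each eligible drug, a propensity score — the
probability that a report lists the drug given the *other* drugs on the
report — is estimated by one of:

* `BIC` — lasso path of the exposure on all other drugs + BIC selection,
  then an unpenalized logistic PS model on the winners;
* `CISL` — CISL with the nonzero constraint at the 10% quantile, then an
  unpenalized refit (intercept-only, i.e. constant PS, when nothing is
  selected);
* `hdPS` — candidates ranked by the Bross multiplicative confounding
  potential `Bias_M = [P_C1(RR−1)+1]/[P_C0(RR−1)+1]` (prevalence of the
  candidate among exposed/unexposed × its risk ratio for the event, 0.1
  added to all four cells of the candidate × event table against zero
  cells); the top 20 by `|log10 Bias_M|` enter the PS model. This is the
  only estimator that depends on the target event, so its scores cannot be
  reused across outcomes;
* `GTB` — gradient tree boosting (xgboost) of the exposure on all other
  drugs, learning rate 0.1, 100 rounds, other settings at library defaults,
  single-threaded with a pinned seed for exact reproducibility.

Scores are clamped to [1e−6, 1−1e−6] so inverse-probability weights stay
finite. The PS then enters one of three association analyses per
(drug, event) pair:

* **adjustment** — logistic fit of the event on (exposure, ê), the PS on
  the probability scale;
* **IPTW** — weights `w = X/ê + (1−X)/(1−ê)` (≥ 1; unbounded for rare
  drugs, which is why this strategy is numerically fragile — an optional
  weight cap is available but off by default);
* **MW** (matching weights) — `w = min(ê, 1−ê)·[X/ê + (1−X)/(1−ê)]`,
  bounded in [0, 1], targeting the estimand of pair matching on the PS.

Weighted fits solve the weight-scaled logistic score equations
(`statsmodels` GLM with `var_weights`). The default standard error is the
robust sandwich with weights treated as fixed, `A⁻¹(Σ w² s sᵀ)A⁻¹`; note
that frequency-weight semantics (a weight-w row as w replicates) would give
`Σ w s sᵀ` in the middle and overstate the variance for MW, whose weights
are ≤ 1 — the test suite checks the resulting one-sided test's null
rejection rate against its nominal level. A model-based variance is
available via `robust=False`. All PS detectors use one-sided
Wald p-values + BH at FDR ≤ 5%, the same decision layer as the univariate
screen. The step-up rule rejects at equality (`p_adj ≤ level`).

AE-independent PS vectors (BIC/CISL/GTB) are estimated once per drug and
shared across the adjust/IPTW/MW strategies through a cache (optionally
on disk).

## Numerical choices

* **Lasso solver.** scikit-learn `liblinear` with `C = 1/λ` (so λ is the
  penalty on the sum-form log-likelihood), warm starts down the grid and
  `random_state` pinned (liblinear shuffles internally). liblinear
  penalizes the intercept through its bias feature; `intercept_scaling=1e4`
  reduces that artefact to ~1e−4, verified against an exact scalar
  coordinate-descent oracle. λ-grid default: 50 log-spaced values from the
  data-driven `λ_max = max_i |X_iᵀ(y − ȳ)|` down to 0.01·λ_max. A grid
  entry of exactly 0 is fitted unpenalized (lbfgs).
* **BIC refits.** `statsmodels` Logit, Newton, 50 iterations; candidates
  that do not converge (quasi-separation) or are singular are skipped with
  a warning. The detectors visit candidate sets in increasing size and stop
  after 10 consecutive non-improving refits (`patience`); the exhaustive
  scan is the default of `bic_select` itself and the behaviour checked in
  tests. The ln N penalty per parameter makes a much larger late winner
  implausible.
* **Degenerate inputs.** Single-class outcomes raise; degenerate exposures
  (all 0/1) raise in PS estimation; zero weighted 2×2 cells or
  non-converged association fits yield NA p-values that pass through BH
  untouched and are excluded from the number of tests m.
* **Tie-breaks.** Ranked-detection curves order by (adjusted p, estimate
  descending, drug code ascending); hdPS top-k ties resolve by candidate
  index.
* **p-value clipping.** One-sided p-values are kept strictly inside (0, 1)
  against floating-point saturation of Φ.

## Synthetic data generator

The generator emulates the features of a national spontaneous-reporting
database that matter for detector behaviour: sparsity, a rare outcome,
co-prescription correlation, and confounding-by-co-prescription. It does
**not** attempt to calibrate to any real database's correlation structure,
and models no report covariates other than drugs (no age/sex), no duplicate
reports, and no reporting trends — so passing tests demonstrate that the
detectors resolve the planted structure, not that they would achieve any
particular performance on real data.

* **Exposure.** Drugs are partitioned into co-prescription blocks. Each
  block has a latent per-report Bernoulli factor with prevalence
  `block_factor_prob` (default 0.1 — a therapeutic context present on 10%
  of reports). A block drug with marginal prevalence p is on with
  probability `p·(1 + a(1−f)/f)` inside the context and `p·(1−a)` outside,
  `a = within_block_corr` (default 0.9): the mixture preserves the marginal
  exactly while concentrating use inside the context (~9× enrichment at the
  defaults), which is what makes co-prescribed drugs share reports. Drugs
  outside blocks are independent Bernoulli.
* **Outcome.** One composite adverse-event column from the logistic model
  with baseline logit(0.05) (a common, well-reported event class) and log
  odds-ratios drawn uniformly from (0.7, 1.5) on the 10 true-signal drugs.
  Each true signal shares its block with one confounded null (zero
  coefficient), so the confounded null's *univariate* log-OR is biased to
  roughly +0.25–0.4 — large enough that an FDR-controlled univariate screen
  regularly flags it, which is precisely the failure mode the multivariate
  and MW-PS detectors are expected to avoid.
* **Defaults.** N = 20,000 reports, I = 200 drugs, drug prevalences
  uniform in (0.01, 0.05), 10 true signals, 10 confounded nulls. The
  block-factor prevalence of 0.1 was fixed at design time so that the
  planted confounding is strong enough to fool a univariate screen (at
  0.25 the within-context enrichment is only ~3× and the induced bias
  drowns in sampling noise).

## Problem sizes used in tests and the acceptance script

Detector-level experiments run at 10–40 drugs and 5,000–20,000 reports —
large enough for the asymptotic Wald/BH machinery to be in its working
regime (hundreds of exposed reports and ≥ 10 expected exposed cases per
drug) and small enough that the full suite runs in minutes on one CPU.
Recovery checks keep the full N = 20,000; null-calibration replicates use
N = 10,000 with 15 drugs.

## Known limitations

* **CISL under a complete null.** With *no* true signals anywhere, the
  data-driven λ-grid anchors to the largest chance association, the whole
  grid spans the null z-range, and the "q-quantile of π̂ > 0" rule retains
  the few covariates whose realized marginal association happens to be
  positive and moderately large (their sign is stable under resampling).
  CISL's documented conservatism presumes real signals anchoring the grid;
  on a fully null database it can emit a handful of chance-positive
  selections. The complete-null FDR guarantee belongs to the p-value-based
  detectors, not to stability selection.
* **BIC-lasso exact-set recovery.** The first spurious covariate to enter
  the path carries the maximum of many selection-biased deviance gains and
  beats the ln N penalty in a non-negligible fraction of replicates
  (~15–20% at n = 5,000 with 50 covariates); the winner then contains the
  true set plus one extra. Detection (the positive-sign rule + reference
  scoring) is barely affected, but exact support recovery should not be
  expected from BIC at these sizes.
* **hdPS variant.** The literature contains several covariate
  prioritization rules; the Bross multiplicative-bias ranking implemented
  here is the standard one, with the recurrence-expansion steps omitted
  because covariates are already single-severity binary indicators.
* **IPTW.** Intentionally fragile for rarely-reported drugs (weights up to
  1/ê); kept as a comparator, with optional trimming exposed but disabled
  by default.
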