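# Methods

This document records the statistical model, the privacy mechanisms, the
parameter defaults and the deliberate design decisions behind
`fedstats`, in enough detail to reimplement it.

## 1. Data model

Each federation node holds one validated patient table (one row per
patient) with a shared schema:

* `patient_id`, `center`, `inclusion_date` (ISO-8601);
* categorical variables `gender` (Female/Male), `age_class`
  (<55 / 55-65 / >65 years), `bmi_class` (<18.5 / 18.5-25 / >25 kg/m²),
  `treatment_category` (Chemotherapy / Chemotherapy+angiogenesis
  inhibitor / Chemotherapy+immunotherapy / Immunotherapy);
* quantitative variables `creatinemia` (µmol/L) and
  `firstline_duration_days`;
* optional day offsets from inclusion: `secondline_start_day`,
  `death_day`, `transfer_day`.

**Period assignment.** The inclusion date maps to `before`
(2019-03-01 … 2020-03-01, closed) or `after` (2020-03-02 … 2021-03-31,
closed); anything outside both windows is a validation error. The
windows are configurable but must be disjoint.

**Outcome derivation.** Progression within the observation window
(default 730 days) is proxied by the earlier of second-line start and
death. The patient's observed span ends at the transfer date if they
changed centers, otherwise at the administrative window. If the proxy
falls inside the span the patient progresses at that day; otherwise they
are censored at the span end, with the censoring reason recorded
(`transfer` or `end_of_window`). The duration analysis excludes
transferred patients entirely; the progression analysis keeps them,
censored at transfer.

## 2. Differential privacy

All mechanisms are pure ε-DP.

* **Laplace mechanism**: a statistic with ℓ1-sensitivity Δ is released
  as value + Laplace(b) with scale b = Δ/ε (noise variance 2b²).
  Sensitivities, all derived from *public* clamp bounds [L, U] (defaults:
  creatinemia [20, 300], durations [0, 1500]): count Δ=1, clamped sum
  Δ=max(|L|,|U|), clamped sum of squares Δ=max(L²,U²), clamped extremum
  Δ=U−L.
* **Derived statistics** split their budget over their components:
  mean = noisy sum / noisy count at ε/2 each; variance from noisy
  (count, sum, sum of squares) at ε/3 each, floored at 0.
* **Quantiles** use the exponential mechanism: the clamped sorted sample
  cuts [L, U] into intervals, interval i (with i values below it) has
  utility −|i − qn| (sensitivity 1) and is chosen with probability ∝
  length·exp(εu/2); the release is uniform inside the chosen interval.
  This is far cheaper in noise than Laplace on an order statistic, whose
  sensitivity would be the whole domain width.
* **Histograms** exploit parallel composition: bins are disjoint, so
  each bin gets independent Laplace(1/ε) noise while the whole table
  costs ε once. Released counts are rounded to nonnegative integers.
* **Post-processing** (rounding, re-clamping into [L,U], flooring noisy
  denominators) is free and used liberally.
* **Composition**: sequential releases add their ε; the
  `BudgetLedger` records every charge per (node, dataset) and only ever
  grows. Local DP charges every node's ledger; central DP (trusted
  coordinator, one draw after pooling) charges a coordinator ledger
  once and needs k× less noise variance than local DP over k nodes.
* **Noise-free mode** (test-only) is the ε→∞ limit: no noise *and* no
  clamping, so every DP operation degenerates to its exact counterpart
  bit-for-bit up to float summation order, while budget accounting is
  unchanged. The test suite asserts this degeneration end to end.

Defaults: ε = 5 per univariate release, ε = 60 for the DP t-test
(split as ε/6 per released statistic per group), giving each node a
total spend of 220 for the full DP study (2 quantitative variables × 5
releases × 5, plus 10 histograms × 5, plus 2 t-tests × 60).

## 3. Disclosure control

Before releasing anything a node checks its *true* (pre-noise) result:

* a filtered subset smaller than `min_subset_n` (default 3) masks the
  whole answer;
* a histogram containing a nonempty cell below `min_cell_count`
  (default 3) masks the whole table. Empty cells pass: a zero count
  singles out no individual, while cells of 1–2 do. This keeps tables
  with structural zeros (e.g. a treatment absent in one period)
  releasable, matching common federated-analytics practice.

A masked node sends a payload-free message; the coordinator pools the
surviving nodes and records a warning, or fails the query if the policy
is strict or every node masked. Because the check runs on true counts,
masking is deterministic and leaks nothing about the noise.

## 4. Statistical inference

* **Chi-square**: Pearson's test with the Yates continuity correction on
  2×2 tables (the correction is what reproduces the study's printed
  p-values; it is switchable).
* **Fisher's exact test** is implemented for general r×c tables with the
  probability-mass two-sided criterion: enumerate every table with the
  observed margins, sum the hypergeometric probabilities of those no
  more probable than the observed one (1e-7 slack against ties lost to
  rounding). Enumeration is capped (default 2·10⁶ tables) with a seeded
  margin-preserving Monte-Carlo fallback. scipy's 2×2 implementation is
  the cross-check oracle in tests.
* **Test selection**: chi-square when every observed cell is ≥ 5,
  Fisher otherwise.
* **Student t-test** (pooled variance, two-sided) is computed purely
  from per-group (n, mean, sd) sufficient statistics, so it runs on
  pooled federation output.
* **DP t-test**: each node releases, per group, a noisy count, clamped
  sum and clamped sum of squares at ε_total/6 each. The coordinator
  pools them into group summaries and — because the Laplace scales are
  public — adds the exact noise variance carried by each group's
  released mean into the t denominator. Without this correction the
  test is anti-conservative (measured type-I ≈ 0.12 at ε=60, n≈75 per
  group; with it ≈ 0.086, and ≈ 0.05 noise-free). Degenerate cases
  (noisy count collapsing to the floor of 2) are flagged.
* **Confounder screening**: covariates with a bivariate p strictly
  below 0.20 against the period enter the adjusted models.

## 5. Federated models

Both models are *exactly* equivalent to their centralized counterparts
because the likelihoods separate over sites; DP is not applied at this
stage (model releases are aggregate p-vectors and p×p matrices).

* **Linear regression**: each node ships (X'X, X'y, y'y, n) on its
  complete cases; the coordinator solves the pooled normal equations,
  recovers σ² = RSS/(N−p) and Student-t 95% CIs. Verified against
  `numpy.linalg.lstsq` and statsmodels to ~1e-8.
* **Stratified Cox**: strata are centers, so risk sets never cross
  nodes. Per Newton iteration each node evaluates the value, gradient
  and Hessian of its stratum's Breslow partial log-likelihood (tied
  event times share a risk set) at the shared coefficients; the
  coordinator sums them and takes a damped Newton step (step-halving,
  gradient tolerance 1e-8, max 50 iterations). Event-free strata are
  dropped. Variance is the inverse observed information; hazard-ratio
  CIs are exp(β ± 1.96·se). Verified against lifelines (which must be
  run at tightened precision, and on tie-free times, since it defaults
  to Efron tie handling) to ~1e-6.
* Dummy coding is reference-based; the reference for `period` is
  `after`, so the period coefficient reads "before vs after".
  Rank-deficient designs fail with the collinear columns named.

## 6. Synthetic cohorts and the fixture

* `generate_cohort` draws stochastic 3-center cohorts (25 patients per
  center per period by default) with category probabilities matching
  the study's observed proportions, normal creatinemia, log-normal
  durations, exponential/Weibull progression times with administrative
  censoring at 730 days and ~3% transfer censoring. It is the engine
  for calibration simulations.
* `build_fixture` deterministically constructs a cohort whose *pooled*
  per-period cross-tabs, quantitative means/SDs (exact, via a bisection
  on a log-space spread that also keeps values positive),
  progression counts and transfer counts reproduce a `MarginalSpec`
  exactly; `table1_spec()` carries the published study's marginals.
  Pooled level counts are split across centers by a seeded constrained
  search that keeps both margins exact while avoiding per-center cells
  strictly between 0 and 3, so each node's occurrence tables clear the
  disclosure check. The per-center allocation is otherwise arbitrary —
  only pooled quantities are specified.

## 7. Reproducibility

Every randomness source descends from one root seed through
`numpy.random.SeedSequence` spawn keys: node i's answer to query q uses
the substream (seed, 2, q, i), central noise (seed, 3, q), the DP
t-test (seed, 4, i), generators (seed, 0, center) and the fixture
(seed, 1). Identical seeds give byte-identical reports; distinct paths
give independent streams. Root seeds are folded modulo 2³¹.

## 8. Limitations

* Pure ε-DP only; no (ε, δ) accounting, no Gaussian mechanism, no
  privacy amplification arguments.
* Pooled quantiles without DP are n-weighted averages of per-node
  quantiles — an approximation that is exact only when node
  distributions coincide.
* The DP t-test's noise correction treats the noisy denominator terms
  as known constants; at very small ε or very small n the noisy count
  floor can still distort the reference distribution (flagged as
  degenerate).
* The Cox implementation supports Breslow ties only, right censoring
  only, and no time-varying covariates.
* Disclosure checking guards single released tables; it does not
  account for cumulative reconstruction across many overlapping
  queries — that is what the DP budget is for.
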