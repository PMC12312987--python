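# fedstats

Federated aggregate statistics with local differential privacy for
multi-center clinical cohorts.

`fedstats` simulates a federation of hospital nodes, each holding its own
patient-level cohort table, and runs a complete retrospective
observational study over them — descriptive statistics, confounder
screening, linear regression and a center-stratified Cox model — while
only ever exchanging aggregate messages. Every release can additionally
pass through pure ε-differential-privacy mechanisms (Laplace and
exponential), with per-node budget accounting, and every node applies
minimum-cell-count disclosure checks before releasing anything.

The study design baked into the defaults is a before/after comparison of
first-line treatment duration and 24-month progression across two
inclusion periods separated by the first COVID-19 wave, over three
centers.

## What the package provides

| Module | Contents |
|---|---|
| `fedstats.cohort` | Harmonized patient table (`CohortTable`), schema validation, period assignment, progression-proxy outcome derivation, CSV and YAML-config I/O |
| `fedstats.synthetic` | Stochastic cohort generator and a deterministic fixture whose pooled tables reproduce a published marginal specification exactly |
| `fedstats.dp` | Laplace mechanism, exponential-mechanism quantiles, DP histograms under parallel composition, additive privacy-budget ledger |
| `fedstats.federation` | `Node` / `Federation` message passing, disclosure policy, exact and noised pooled queries (count, sum, mean, SD, min/max, quantiles, histograms) |
| `fedstats.inference` | Yates-corrected chi-square, exact r×c Fisher test, pooled-variance t-test from sufficient statistics, its noise-aware DP counterpart, p < 0.20 confounder screening |
| `fedstats.models` | Federated OLS (exact) and center-stratified Cox proportional hazards via distributed Newton-Raphson (exact) |
| `fedstats.pipeline` | End-to-end study orchestration and JSON/Markdown reporting |
| `fedstats.cli` | `fedstats simulate / fixture / run / budget` commands |

## Quick start

```sh
# write the deterministic three-center fixture cohort
fedstats fixture --out-dir fixture --seed 0

# run the full study without DP
fedstats run --nodes fixture/toulouse.csv --nodes fixture/reims.csv \
             --nodes fixture/foch.csv --out-dir report

# same run under local differential privacy (seeded, reproducible)
fedstats run --dp --seed 1 --nodes fixture/toulouse.csv \
             --nodes fixture/reims.csv --nodes fixture/foch.csv \
             --out-dir report_dp --dump-messages
fedstats budget --report report_dp/report.json
```

On the fixture cohort the non-DP run reports, among other things:
75 and 74 patients included before/after, 72 patients per period in the
duration analysis after excluding transfers, pooled first-line duration
mean 217.2 days, pooled creatinemia mean 65.5 µmol/L, a period
comparison p-value of .21 for progression and .79 for gender (Yates
chi-square), <.001 for treatment category (exact Fisher test, forced by
a zero cell), and `treatment_category` as the only covariate passing the
p < .20 screen. The adjusted hazard ratio of progression for the before
period is 1.16 (95% CI 0.78–1.73). The DP run additionally annotates
every released cell with its ε and ends with each node's ledger at
ε = 220 in total (ε = 5 per univariate release, ε = 60 per DP t-test).

The same study is scriptable:

```python
from fedstats import RunConfig, build_fixture, run_full_study, table1_spec

tables = build_fixture(table1_spec(), seed=0)
report = run_full_study(tables, RunConfig(seed=1, dp=True))
print(report["bivariate"]["p_values"])
print(report["ledger"]["per_node"])   # {'toulouse': 220.0, ...}
```

## Privacy model

* **Local DP** (`dp="local"` / `--dp`): each node perturbs its own
  sufficient statistics with Laplace noise calibrated to
  sensitivity/ε before sending. No party ever sees exact counts.
* **Central DP** (`dp="central"`): nodes send exact aggregates and a
  trusted coordinator adds one noise draw after pooling — for k nodes
  this needs k× less noise variance at the same ε.
* Budgets compose additively and only ever grow; post-processing
  (clamping, rounding) is free. Disclosure checks always run on the
  *true* counts, so masking never depends on a noise draw.
* t-test inference on DP releases accounts for the publicly known noise
  variance of the released group means; ignoring it would be
  anti-conservative.

See `docs/methods.md` for the statistical model, the sensitivity
derivations, parameter defaults and limitations.

## Testing

```sh
python -m pytest -q tests/
```

The suite covers every module against independent oracles: scipy for the
2×2 Fisher and t tests, `numpy.linalg.lstsq`/statsmodels for the
federated OLS, lifelines for the stratified Cox model, finite
differences for the Cox gradient/Hessian, and Monte-Carlo calibration
checks for the DP mechanisms (noise variance, tail probabilities,
local-vs-central variance ratio, type-I error of the DP t-test).

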