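# prscreen

Screening performance calculus for polygenic risk scores (PRS) under a
two-Gaussian equal-variance model.

Published PRS discrimination metrics — odds ratio per SD, hazard ratio
per SD, AUC, C-index — say little about screening usefulness on their
own. `prscreen` converts any of them into a single model parameter (the
standardized mean difference `delta` between the score distributions of
affected and unaffected individuals) and derives from it the quantities
that matter for screening, individual prediction and stratification:

- **Detection rate** at any false positive rate (e.g. DR at 5% FPR),
  and the inverse query: the metric required for a target detection rate.
- **Likelihood ratios** in three constructions — threshold (DR/FPR),
  centile (density ratio at a score value), and quantile group (area
  ratio) — and the posterior **odds of becoming affected** obtained by
  multiplying a background odds.
- **Stratification tables**: per-quantile-group likelihood ratios, odds
  and integer head counts for a hypothetical cohort.
- **Catalogue pipeline**: parse a PGS-Catalog-style performance-metrics
  TSV, apply plausibility filters (drop continuous traits, OR/HR per SD
  < 1, AUC < 0.5, implausible C-index), and summarize DR at 5% FPR by
  trait or metric kind.
- **Interventions**: detection/false-positive rates from published 2×2
  cohort counts, events prevented under a treatment model, number
  needed to genotype, and an integer-accounted two-stage screening flow
  (score triage followed by a confirmatory test).
- **Synthetic data**: seeded individual-level cohorts from the generative
  model plus mock catalogue tables with exact ground-truth manifests.

## CLI

The `prscreen` console script (equivalently `python -m prscreen.cli`)
exposes the calculators. Human-readable output by default; `--json`
yields machine-readable payloads with full precision. Exit codes:
0 success, 2 validation error, 3 I/O error.

```sh
# metric conversion and detection rate
prscreen convert --metric auc=0.8 --fpr 0.05 --odds 1:19
prscreen convert --target-dr 0.8 --fpr 0.05          # required performance

# individual odds at score centiles (unaffected distribution)
prscreen predict --delta 0.48 --odds 1:19 --centile 2.5 --centile 97.5

# quintile-group stratification of a 100 000-person cohort
prscreen stratify --delta 0.48 --odds 1:19 --groups 5 --population 100000

# upper-tail analysis and top-vs-bottom odds ratios
prscreen tails --delta 0.48 --odds 1:19 --fraction 0.025

# catalogue pipeline on a performance-metrics TSV
prscreen catalog metrics.tsv --group-by metric_kind --json

# intervention scenarios from a JSON file
prscreen intervene --scenario scenario.json --json
```

Scenario files for `intervene` are JSON objects. Two kinds:

```json
{"kind": "two_stage", "n_cohort": 100000, "background_odds": "1:64",
 "delta": 0.486, "top_fraction": 0.025, "stage2_dr": 0.75, "stage2_fpr": 0.08}
```

```json
{"kind": "nng", "cohort": 100000, "events_above_cutoff_with": 4870,
 "events_above_cutoff_without": 4783, "relative_risk_reduction": 0.2,
 "total_events": 8000}
```

Odds are written `a:b`, as a decimal probability, or as a percentage
with an explicit `%` suffix. Centiles are percent by default in the CLI;
the API takes an explicit unit (`CentileQuery.from_percent` /
`from_fraction`).

## Library example

```python
from prscreen import (
    ReportedMetric, ScreeningCut, Odds,
    delta_from_metric, detection_rate, odds_given_positive,
)

model = delta_from_metric(ReportedMetric("auc", 0.8))
cut = ScreeningCut.from_fpr(0.05)
detection_rate(model, cut)                     # 0.325
odds_given_positive(model, cut, Odds(1, 19)).one_in_n()  # "1:3"
```

## Notes on conventions

- Hazard ratios per SD are converted like odds ratios (`delta = ln HR`);
  the C-index is treated as an AUC. Both are documented assumptions.
- Centiles/quantiles always refer to the **unaffected** distribution.
- Display rounding (whole percentages, integer `1:N` odds denominators,
  ties away from zero) happens at the presentation layer only.
- Integer head counts in tables and flows use largest-remainder repair
  so totals are conserved exactly.
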