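# claimcase

Rule-based case ascertainment over health administrative claims, with
diagnostic-accuracy evaluation and a seeded synthetic-cohort simulator.

The package implements the family of case-definition algorithms used in
administrative-data validation studies of rheumatoid arthritis: counts of
RA-coded physician billing claims inside temporal windows (with minimum gaps
between counted claims, musculoskeletal-specialist requirements and
co-occurring drug-claim requirements), OR'd with hospital/ER discharge-code
branches, and optional exclusion rules. Algorithm output is scored against a
chart-review reference standard to produce sensitivity, specificity,
predictive values and prevalences with 95% confidence intervals, plus a
lexicographic (PPV, sensitivity, specificity) ranking.

## Layout

| module                 | contents                                                        |
| ---------------------- | --------------------------------------------------------------- |
| `claimcase.model`      | domain types (patients, claims, labels) and cohort CSV I/O      |
| `claimcase.codesets`   | RA / other-rheumatology / specialty / drug-class classification |
| `claimcase.engine`     | clause evaluation, window logic, exclusions, algorithm DSL      |
| `claimcase.stats`      | confusion tables, metrics, Wald/Wilson/Clopper–Pearson CIs, ranking |
| `claimcase.simulate`   | seeded synthetic cohort generator and planted-truth audit       |
| `claimcase.cli`        | `simulate` / `evaluate` / `rank` / `compare` pipeline           |

Bundled data (`src/claimcase/data/`):

- `algorithms.json` — 43 algorithm definitions in the DSL (28 whole-cohort,
  15 drug-requiring definitions restricted to ages ≥65),
- `code_config.yaml` — default code sets (the "other rheumatology" lists are
  implementer-supplied defaults; override freely),
- `validation_tables.csv` — published confusion-table cells and rendered
  metrics for the 43 algorithms, used by the regression tests and the
  acceptance report. One cell (FP of `p3_any_2y`) is corrected from an
  internally inconsistent source value (54 → 36; the row's own PPV,
  specificity, post-test prevalence and cohort total all imply 36).

## Algorithm DSL

```
1H                               one hospitalization RA code, ever
1H | 1E                          hospitalization OR emergency-room code
3P(spec>=1)/2y                   3 physician claims, >=1 by a specialist, within 2 years
1H | 2P(gap>=56d)/2y excl(A,B)   OR of clauses, 8-week gap, exclusion cases A+B
2P(gap>=60d,rx>=1)               2 claims >=60 days apart plus a drug claim, ever
```

Windows are inclusive day spans (1y = 365 d). Same-day claims collapse to one
qualifying date. Drug-requiring clauses evaluate only for patients aged ≥65 at
the index date (2010-12-31); under a `/Wy` window, the physician claims and
the drug claim must fit inside a single interval of length W.

## CLI

```bash
claimcase simulate --seed 42 --out cohort/            # writes 5 CSVs
claimcase evaluate --cohort cohort/ \
    --algorithms src/claimcase/data/algorithms.json \
    --mode definite_only --subset seniors --out results/
claimcase rank --results results/results.json --min-sens 75
claimcase compare runA/results.json runB/results.json
```

Exit codes: 0 success, 2 configuration error, 3 data error. `evaluate`
refuses drug-requiring algorithms under `--subset adults` because drug
claims are only observed for seniors.

## Rendering convention

Printed metric cells use two-stage rounding: percent → one decimal
(half-up) → integer (half-up), so 31.47 renders as `32`. Exact rational
arithmetic is kept until rendering; undefined measures (zero denominators)
propagate as `NA`, never as 0 or 100.
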