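# dishare

Cross-cohort penalized regression with *discrepancy partitioning*: two
drug-screening cohorts (G and C) are modeled jointly with shared
coefficients `beta` plus a sparse cohort-discrepancy vector `delta`
(`y = X beta + e` on G, `y = X (beta + delta) + e` on C), estimated by an
adaptive weighted elastic net. Shrinkage zeroes out small discrepancies,
so concordant signal and cross-study disagreement are separated — giving
both accurate test-set predictions and reproducible drug–gene interaction
signatures from potentially inconsistent paired studies.

The package provides:

- `dishare.core` — model types (`CohortPair`, `PenaltySpec`, `SharedFit`),
  the penalized objective, a stacked-design reduction, a coordinate-descent
  solver with per-coordinate penalty factors (numba-accelerated, with a
  pure-Python reference engine), the two-stage adaptive fit
  (`fit_shared`), formulation transforms and prediction.
- `dishare.tuning` — (λ1, λ2) selection by k-fold cross-validation over a
  log-spaced grid, stratified by cohort.
- `dishare.screening` — per-cohort sure-independence screening with union
  of the top-k marginal-correlation picks.
- `dishare.preprocess` — missingness filters (samples with >10000 missing
  values, features with missing rate >0.3), mean imputation and
  mean-0/variance-1 standardization with training-scale transforms.
- `dishare.simulate` — AR(1)-correlated synthetic cohort generator with
  block-sparse shared effects and sparse discrepancies, plus the
  replicated comparison study against individual-cohort and pooled
  baselines.
- `dishare.stability` — repeated-CV stability runs (selection frequency
  and average coefficient per feature), the frequency ≥ 80% / ±2 s.d.
  marker-inclusion rule, and cross-drug signature matrices with heatmap
  rendering.
- `dishare.evaluate` — test-error evaluation, five-number summaries and
  the boxplot-comparison statistic DBM/OVS (distance between medians over
  overall visible spread, with a disjoint-IQR significance shortcut), and
  the repeated-split method comparison.
- `dishare.cli_io` — the `dishare` command-line interface, delimited-text
  readers/writers and a synthetic paired-cohort fixture generator.

## Command-line usage

```sh
# synthetic paired-cohort fixture (feature/response tables + truth file)
dishare fixture --seed 1 --preset small --out out/fixture

# replicated simulation study (reduced scale by default)
dishare simulate --seed 1 --replicates 50 --out out/sim

# full per-drug pipeline: preprocess -> screen -> fit -> stability -> signature
dishare analyze \
  --features-g out/fixture/features_G.tsv --responses-g out/fixture/responses_G.tsv \
  --features-c out/fixture/features_C.tsv --responses-c out/fixture/responses_C.tsv \
  --seed 1 --out out/analysis

# repeated-split test-error comparison for one drug (DBM/OVS report)
dishare evaluate \
  --features-g out/fixture/features_G.tsv --responses-g out/fixture/responses_G.tsv \
  --features-c out/fixture/features_C.tsv --responses-c out/fixture/responses_C.tsv \
  --drug drugA --seed 1 --scenario 2 --out out/eval
```

Feature tables are TSV/CSV with a header of feature ids and a first
column of cell-line ids; missing entries are empty or `NA`. Feature kinds
come from the id prefix (`mut_`, `cnv_`, `tissue_`, otherwise
expression). Response tables have columns `cell_line`, `drug`,
`response_value`. Every command echoes its resolved configuration and a
provenance log (input checksums, versions, wall clock) next to its
outputs, and is deterministic given `--seed`.

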