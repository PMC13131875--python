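# epicohort

A toolkit for building and evaluating disease-classification and
gene–environment analyses on synthetic survey + genotype cohorts. It
bundles:

- **`epicohort.syncohort`** — synthetic cohort generation with known ground
  truth: participant demographics and QC flags, admixed genotype dosages
  (Balding–Nichols population structure), three mixed-type survey tables with
  block/skip/item missingness, a logistic-liability binary outcome with
  configurable genetic, environmental, interaction, and confounder effects,
  simulated harmonized PGS weight files, and a sequential per-column table
  synthesizer (tree-based) that preserves within-table marginals while
  destroying cross-table correlation.
- **`epicohort.splitkit`** — QC filtering (outlier / relatedness / race-mismatch
  flags) and a genotype-availability-stratified thirds split with a
  deterministic remainder rule (remainder to train, then validation).
- **`epicohort.survey_prep`** — auditable survey preprocessing: skip-fills for
  gated questions, strict missingness/mode-frequency variable filters,
  collinearity and exclusion-list screens, frozen train-only
  median/mean/mode imputation, and invertible ordinal/binary encoding.
- **`epicohort.exwas_net`** — per-exposure logistic association screen and
  correlation-network feature selection (edges where |r| > threshold, one
  max-odds-ratio representative per connected component).
- **`epicohort.pgslib`** — polygenic scores from harmonized scoring files
  (tab-separated: `rsID, chr_name, chr_position, effect_allele, other_allele,
  effect_weight`) with allele matching/flipping, skip-and-count policy for
  unmatched variants, frozen z-standardization, and a single-score benchmark
  classifier.
- **`epicohort.hybrid_stack`** — survey-only probabilistic baseline (random
  forest or gradient boosting), logistic stacking over the baseline
  probability plus m standardized PGS, and a missing-genetics branch that
  returns the baseline probability unchanged.
- **`epicohort.gxe_scan`** — per-(variant, environment) marginal and
  interaction regressions (linear-probability default, logistic optional),
  MAF filtering, genotype PCA covariates, and ranking of pairs by their
  externally studentized deviation from the conditional-vs-marginal effect
  regression.
- **`epicohort.metrics`** — from-scratch AUROC (Mann–Whitney, ties = ½) and
  AUPRC (step-wise average precision), leaderboard ranking with the AUPRC
  tiebreak, and strict two-column submission-CSV round-trip.

## CLI

All stages are exposed as subcommands of `epicohort` (logs to stderr,
results to files, `--seed` drives every stochastic stage):

```bash
epicohort simulate --config cohort.yaml --out cohort/ --seed 1
epicohort split --in cohort/ --seed 1 --out splits.tsv
epicohort prep --in cohort/ --splits splits.tsv --out encoded.tsv --report drops.tsv
epicohort exwas --features encoded.tsv --outcome cohort/outcome.tsv --out exwas.tsv
epicohort select-features --features encoded.tsv --exwas exwas.tsv --out reps.txt
epicohort pgs-score --in cohort/ --weights weights/ --out pgs.tsv
epicohort train-hybrid --in cohort/ --splits splits.tsv --pgs pgs.tsv \
    --seed 1 --out model.json --submission submission.csv
epicohort gxe-scan --in cohort/ --out pairs.tsv
epicohort score-submission --submission submission.csv --truth test_truth.tsv
epicohort leaderboard --submissions a.csv --submissions b.csv \
    --truth test_truth.tsv --out board.tsv
```

A cohort directory is plain text throughout: TSV tables, a JSON truth
file, an optional minimal VCF.

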