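# mrmediate

Two-sample Mendelian randomization (MR) and mediation analysis toolkit for
GWAS summary statistics, with a synthetic three-node study generator so the
whole pipeline is testable offline.

## What it does

- **Summary-statistics I/O & harmonisation** (`mrmediate.summary_stats`):
  read/validate/write tab-separated GWAS tables (canonical columns
  `snp_id chrom pos effect_allele other_allele eaf beta se pval n`), align
  exposure/outcome effect pairs onto a common effect-allele frame (allele
  swaps, strand complements, palindromic-SNP handling with an EAF
  ambiguity band).
- **Instrument selection** (`mrmediate.instruments`): p-value threshold,
  greedy LD clumping (r² threshold within a distance window, deterministic
  tie-breaking), per-variant F-statistic filtering, and Steiger filtering
  of variants that explain more outcome than exposure variance.
- **Five causal estimators** (`mrmediate.estimators`): Wald ratio, IVW
  (fixed / multiplicative-random), Egger regression with intercept test,
  weighted median (bootstrap SE), simple and weighted mode (kernel-density,
  bootstrap SE), all reported as OR with 95% CI.
- **Sensitivity suite** (`mrmediate.sensitivity`): Cochran's Q
  heterogeneity, Egger-intercept pleiotropy test, leave-one-out, funnel
  data, Steiger directionality test.
- **Mediation** (`mrmediate.mediation`): six directional MR assessments for
  an exposure → mediator → outcome triple; mediated effect = β1·β2, direct
  effect = β_all − β_mediation, mediated proportion = β_mediation/β_all;
  sign-concordance pathway screening.
- **Batch screening** (`mrmediate.screening`): many exposures against one
  outcome, Benjamini–Hochberg q-values, protective/risk classification,
  deterministic TSV report tables.
- **Synthetic data** (`mrmediate.synthetic`): individual-level three-node
  cohorts (configurable pleiotropy, LD blocks, confounding, binary outcome
  with extreme case-control imbalance) with marginal per-SNP summary
  statistics and a ground-truth sidecar.

A note on scale: binary outcomes use per-SNP linear-probability regression,
and `exp(beta)` is reported as an odds ratio without rescaling. This
mirrors case-control GWAS sources whose near-unity "ORs" indicate
linear-probability effects rather than log-odds.

## CLI

One entry point with a subcommand per stage:

```sh
mrmediate simulate --config sim.yaml --out fixtures/
mrmediate select-instruments --exposure X.tsv --ld ld.tsv \
    --p-threshold 5e-6 --r2 0.001 --kb 10000 --f-min 10 --min-snps 1
mrmediate mr --exposure X.tsv --outcome Y.tsv --ld ld.tsv --seed 17 --out results.tsv
mrmediate sensitivity --harmonized h.tsv --n-exposure 8091 --n-outcome 172171 --out report/
mrmediate mediate --exposure X.tsv --mediator M.tsv --outcome Y.tsv \
    --ld ld.tsv --seed 17 --out mediation.tsv
mrmediate screen --exposures dir/ --outcome Y.tsv --ld ld.tsv --config run.yaml --out report/
```

LD matrices are TSV (square with header row/column, or long
`snp_a snp_b r2`). Analysis thresholds live in a YAML config mirroring
`mrmediate.config.AnalysisConfig` (defaults: p < 5e-6, clump r² = 0.001
within 10,000 kb, F > 10, min 1 SNP with Wald-ratio fallback).

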