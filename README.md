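# mrkit

Bidirectional two-sample Mendelian randomisation (MR) from GWAS summary
statistics. Given per-variant association tables for an exposure and an
outcome trait, `mrkit` harmonises alleles (with LD-proxy substitution and
palindromic-variant handling), screens instrument strength, estimates the
causal effect on the log-odds scale via per-SNP Wald ratios pooled by
IVW fixed/random effects, weighted median, weighted mode and MR-Egger
(with SIMEX dilution correction), and diagnoses pleiotropy through
Cochran's Q / I², per-variant Q contributions with outlier removal and
refit, and leave-one-out analysis. A seeded synthetic-data generator with
known causal slope and configurable pleiotropy backs every estimator with
parameter-recovery experiments.

## Command line

The console script `mr` has four subcommands:

```sh
# one MR direction; flags or a YAML config (flags win)
mr run --exposure exposure.tsv --outcome outcome.tsv \
       --proxies proxies.tsv --out results/ --seed 1

# both directions from two YAML configs
mr bidirectional --forward-config fwd.yaml --reverse-config rev.yaml --out results/

# synthetic two-sample summary statistics with known truth
mr simulate --k 19 --beta 0.4 --scenario directional --mu-alpha 0.05 \
            --tau 0.02 --seed 7 --out-prefix sim/run1

# estimator recovery experiment (bias / RMSE / coverage / rejection)
mr recover --k 19 --beta 0.4 --scenario balanced --tau 0.1 \
           --replicates 500 --methods IVW-FE,WMe,Egger --seed 7 --out rec.json
```

Summary-statistics files are tab-separated with a header; canonical columns
are `variant_id, effect_allele, other_allele, eaf, beta, se, pval`, and
common aliases (`SNP, EA, OA, EAF, BETA, SE, P`, ...) are recognised, or an
explicit column map can be passed via the API. Proxy maps are TSVs with
`target_id, proxy_id, r2, proxy_effect_allele, target_effect_allele`.
Outputs are per-direction TSV tables (estimates on both log-odds and
odds-ratio scales, heterogeneity, Q contributions, leave-one-out, exclusion
log) plus one JSON summary; identical inputs and seed give byte-identical
output.

## Library layout

- `mrkit.sumstats` — reading/validation, harmonisation, proxy substitution,
  F-statistic screening
- `mrkit.estimators` — Wald ratios, IVW-FE/RE, weighted median/mode,
  MR-Egger, SIMEX, odds-scale conversion
- `mrkit.diagnostics` — Cochran's Q, I² with CI, Q contributions, outlier
  refit, leave-one-out, I²_GX
- `mrkit.simulate` — synthetic two-sample generator and recovery harness
- `mrkit.pipeline` — orchestration and reporting used by the CLI

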