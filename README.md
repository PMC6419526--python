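# salmon

Survival prognosis from multi-omics data with a multi-branch Cox
proportional-hazards network over co-expression module eigengenes.

The pipeline:

1. **preprocess** — drop the lowest-20% mean-expression genes, then the
   lowest-20% variance genes.
2. **coexpression** — mine overlapping quasi-clique modules from the
   (Spearman) correlation network with spectral-style weight normalisation,
   and summarise each module into its first right-singular-vector
   "eigengene".
3. **coxnet** — a small neural network in which each omics block (mRNA
   eigengenes, miRNA eigengenes, burden covariates, clinical covariates)
   feeds its own forward branch; branch outputs are merged by a final linear
   Cox layer trained by Adam on the negative log partial likelihood
   (Breslow ties) plus an L1 penalty.
4. **evaluate** — Harrell's concordance index, Kaplan-Meier curves,
   two-group log-rank test, median-risk dichotomisation, paired t-tests.
5. **importance** — zero-ablation feature importance ranked by median
   c-index drop across folds, feature-selection retraining, age-stratified
   runs.
6. **experiments** — 5-fold cross-validation harness with the six
   omics-combination designs and concatenated-fold survival analysis.
7. **synthetic** — seeded generators for latent-factor expression blocks and
   proportional-hazards event times with uniform right censoring, so every
   stage is testable without external data.

The network is implemented directly in NumPy (hand-derived analytic
gradients + Adam); at the problem's scale (tens of inputs, a 17-unit Cox
layer) this trains 5-fold CV in under a second.

## CLI

```bash
# filter expression tables
salmon preprocess --mean-frac 0.2 --var-frac 0.2 expr.tsv filtered.tsv

# mine modules and write eigengenes
salmon coexpress --gamma 0.7 --lambda 1 --t 1 --beta 0.4 --min-size 10 \
    --corr spearman expr.tsv modules.json eigengenes.tsv

# generate a synthetic cohort (TSV + truth.json)
salmon synth --spec spec.yaml --out cohort/

# fit one model on a data directory (mrna.tsv [mirna.tsv] clinical.tsv)
salmon train --config config.yaml --seed 7 cohort/ model.json

# full cross-validated combination experiment with a report
salmon run --combo vi --folds 5 --seed 7 --config config.yaml cohort/ report/
```

`config.yaml` may set `preprocess: {mean_frac, var_frac}`, per-block mining
parameters (`lmqcm_mrna: {gamma: 0.7, ...}`, `lmqcm_mirna: {...}`), training
options (`train: {epochs, batch_size, learning_rate, l1_lambda}`) and hidden
widths (`hidden: {mrna: 8, mirna: 4}`).

Combination labels: `i` = mRNA modules only, `ii` = miRNA only,
`iii` = mRNA+miRNA, `iv` = +burden (CNB, TMB), `v` = mRNA+miRNA+clinical,
`vi` = everything, `covariates_only` = burden+clinical reference.

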