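# txpattern

Detect and categorize transcriptional patterns associated with loss of
wild-type activity in cancer driver genes.

Given a tumour cohort — a TPM expression matrix, per-sample SNV/INDEL calls
with consequence annotations, gene-level copy-number calls, optional
structural variants, and sample metadata — `txpattern`:

1. **labels** every sample per driver gene as *mutant* (impactful
   SNV/INDEL, qualifying CNA, or SV depending on the alteration setting),
   *wildtype*, or *excluded* (only non-impactful variants);
2. **classifies** expression profiles with random forests (stratified
   5-fold CV, F1 with wild-type as the positive class, 90/10 holdout
   overfit screen, per-tumour-type F1);
3. **selects an analysis mode** per gene: CNA labels are adopted only when
   they substantially improve F1; tumour types are selected by a z-test
   threshold on per-type F1; pan-cancer, specific-type, and class-balanced
   modes are compared over repeated permutations with a >5% improvement
   rule, followed by iterative tumour-type pruning;
4. **analyzes features** of the final model: chromosomally proximal
   features (cis-dosage confounds of copy-number events) are iteratively
   excised, Gini importances are calibrated against a label-permutation
   null, each gene's pattern is categorized (*pan-cancer*,
   *tumour-specific*, *no-or-weak*, *potential-overfit*), and the top-15
   features get signed directions from decision-path attributions
   cross-checked against a rank-correlation fallback;
5. **re-examines excluded samples**: the final model predicts the status of
   samples carrying only non-impactful variants, flagging consequence terms
   (e.g. intronic) whose carriers are predominantly called mutant.

A synthetic-cohort generator (`txpattern.synthetic`) produces inputs with
the statistical structure the analysis assumes — tumour-type baselines,
driver-conditional signature shifts, cis dosage around CNAs, per-type class
imbalance, and cryptically impactful "silent" variants — so the entire
pipeline is testable without any external data.

## CLI

```sh
# generate a cohort (tab-separated tables + truth.json)
txpattern simulate --config examples/cohort.yaml --out data/ --seed 1

# label samples for one gene under one alteration setting
txpattern label --cohort data/ --gene PAN --setting snv_cna --out labels.tsv

# run the full per-gene pipeline for several genes
txpattern run-all --cohort data/ --genes PAN,SPEC,NULLDRV \
    --config examples/pipeline.yaml --seed 1 --out results/
```

Other subcommands: `select-mode`, `train`, `analyze`, `predict-excluded`
(see `txpattern --help`). `run-all` writes `ledger.json` (the complete
audit trail: seeds, thresholds with their source populations, mode margins,
excised regions, categories), one `<gene>.report.json` and
`<gene>.features.tsv` per gene, and wall-clock timings to a separate
`timings.log` so repeated runs under one seed are byte-identical.

Pipeline knobs (forest size, permutation counts, thresholds alphas,
proximity-filter geometry, improvement margins) live in a YAML consumed by
`--config`; see `txpattern.pipeline.PipelineConfig` for the full list and
defaults. The variant-consequence vocabulary ships in
`src/txpattern/data/consequence_impact.yaml` and can be replaced per MAF
dialect; unknown terms are hard errors.

## Layout

```
src/txpattern/
  synthetic.py   cohort generator + configs (CohortConfig, DriverSpec)
  cohort.py      containers + TSV/JSON round-tripping
  labeling.py    consequence impact classes, per-gene label sets
  classifier.py  RF primitives: CV, F1, holdout, per-type F1, final fit
  modes.py       thresholds, type selection, balancing, mode comparison
  features.py    proximity filter, Gini null, categories, attributions
  pipeline.py    orchestration, excluded-sample prediction, QC, ledger
  cli.py         click command group
```
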