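# Example synthetic-cohort configuration for `txpattern simulate`.
n_samples: 300
n_genes: 500
n_coding: 250
noise_sd: 1.0
baseline_sd: 0.5
seed: 1
tumour_types:
  - {name: TTA, proportion: 0.25}
  - {name: TTB, proportion: 0.25}
  - {name: TTC, proportion: 0.25}
  - {name: TTD, proportion: 0.25}
drivers:
  - gene_id: PAN
    pattern_kind: pan_cancer
    signature_genes: 20          # integer: generator picks off-window coding genes
    effect_size: 1.5
    mutant_fraction_per_type: 0.35
    nonimpactful_fraction: 0.1
    cryptic_fraction: 0.3
  - gene_id: SPEC
    pattern_kind: tumour_specific
    affected_types: [TTA, TTB]
    signature_genes: 20
    effect_size: 1.5
    mutant_fraction_per_type: 0.35
  - gene_id: "NULLDRV"
    pattern_kind: "null"
    effect_size: 0.0
    mutant_fraction_per_type: 0.35
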