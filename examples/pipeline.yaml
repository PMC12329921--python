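# Example pipeline configuration for `txpattern run-all --config ...`.
# Values here are desk-scale; library defaults are heavier (1000 trees,
# 30 mode permutations, 50 Gini-null permutations).
settings: [snv, snv_cna]
k_folds: 5
cna_epsilon: 0.01
n_perm_modes: 5
select_alpha: 0.5          # tumour-type selection threshold = pooled mean
improvement: 0.05          # relative F1 gain required to narrow the mode
prune_delta: 0.05
gini_n_perm: 20
gini_alpha: 0.05
alpha_f1: 0.1
alpha_gini: 0.25
top_k: 15
pooled_type_threshold: false
rf:
  n_estimators: 100
  max_features: sqrt
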