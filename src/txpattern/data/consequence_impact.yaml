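# Default variant-consequence -> impact-class vocabulary.
# Unknown terms are hard errors; extend this file for other MAF dialects.
impactful:
  - stop_gained
  - nonsense
  - missense
  - missense_variant
  - frameshift
  - frameshift_variant
  - splice_site
  - splice_acceptor_variant
  - splice_donor_variant
  - inframe_insertion
  - inframe_deletion
  - stop_lost
  - start_lost
non_impactful:
  - synonymous
  - synonymous_variant
  - 5_utr
  - 5_prime_utr_variant
  - 3_utr
  - 3_prime_utr_variant
  - intron
  - intron_variant
  - upstream
  - upstream_gene_variant
  - downstream
  - downstream_gene_variant
  - intergenic
  - intergenic_variant
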