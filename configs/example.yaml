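# Example end-to-end configuration for `poeseq run`.
# Omit the `simulate` block and provide `inputs` paths to analyse real tables.

seed: 7

simulate:
  n_genes: 2000
  replicates_per_cell: 3     # mice per genotype x diet cell
  snps_per_gene: 5
  depth: 50                  # mean allelic read depth per SNP x mouse
  overdispersion_rho: 0.02   # beta-binomial extra-binomial variance

# inputs:                    # used when `simulate` is absent
#   counts: data/counts.tsv
#   meta: data/sample_meta.tsv
#   allelic: data/allelic_counts.tsv
#   annotation: data/imprint_annotation.tsv

de:
  p_max: 0.05
  fold_min: 2.0
strain_fold_min: 5.0

screen:
  min_avg_depth: 10
  strict_fraction: 0.99
  majority: 0.50
  min_gap: 0.20
  alpha: 0.05
  min_snps_mild: 4
  min_snps_strict: 1
  t_variant: student         # or welch
  strict_per_sample: false   # true: 99% rule applied to every mouse

flags:
  test_variant: moderated    # or student / welch
  fold_basis: linear         # or log
  bh_correct: false
  min_mean_count: 5
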