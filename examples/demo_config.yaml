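# End-to-end demo: 3 synthetic promoters, 4 conditions, depth 1e5.
# Seeds are mandatory; every stage section mirrors the module defaults.
seed: 11
design:
  n_synthetic_promoters: 3
  n_variants: 1500
  mutation_rate: 0.1
  barcode_length: 20
  barcodes_per_variant: 3
simulate:
  conditions: [glucose, arabinose, stationary, salt_shock]
  active_conditions: [arabinose]
  architecture: default
  depth_dna: 100000
  depth_rna: 100000
  n_replicates: 2
map:
  min_support: 3
  max_edit_distance: 20
footprint:
  pseudocount: 0.5
discover:
  kernel_sigma: 3.0
  cv_ratio_threshold: 0.5
  activity_threshold: 0.002
cluster:
  replicate_floor: 0.3
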