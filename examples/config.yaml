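# Full-pipeline configuration for `metasandy run --config examples/config.yaml`.
# Either give counts_csv/taxonomy_csv/sites_csv for real tables, or a
# `simulate` block to generate a synthetic study in place.
output_dir: metasandy_out
simulate:
  n_beaches: 24
  n_transects: 3
  n_levels: 8
  n_species: 60
  rank: 5
  loading_scale: 0.6
min_rel: 0.0003        # per-sample relative-abundance filter (strict <)
min_reads: 3000        # sample depth filter (strict <)
min_occupancy: 10      # OTU must occur in >= this many composites
r_max: 0.7             # correlation-pruning threshold
vif_max: 2.0           # stepwise VIF threshold
gdm_splines: 3
jsdm:
  mc_samples: 100
  iterations: 500
  rank: 10
  patience: 10
  reduce_factor: 0.9
partition_method: shapley
quantreg_degree: 2
n_boot: 1000
seed: 1
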